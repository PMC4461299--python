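"""Reading and writing the package's TSV dialects and config files.

Expression matrices are tab-separated with a ``gene_id`` first column and
one column per sample; group maps and truth tables are two-column TSVs.
Configs are YAML or JSON mappings with the field names of
:class:`~degbench.simulate.SimulationConfig`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import ExpressionSet, GroundTruth, InputError, TRUTH_LABELS
from .simulate import SimulationConfig


def write_expression(expr: ExpressionSet, path, groups_path) -> None:
    expr.values.to_csv(path, sep="\t", float_format="%.6f")
    expr.groups.rename_axis("sample_id").to_csv(groups_path, sep="\t")


def write_truth(truth: GroundTruth, path) -> None:
    truth.label_of.rename_axis("gene_id").to_csv(path, sep="\t")


def read_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "label"]:
        raise InputError(f"{path}: expected columns gene_id, label")
    bad = set(df["label"]) - set(TRUTH_LABELS)
    if bad:
        raise InputError(f"{path}: unknown labels {sorted(bad)}")
    return GroundTruth(df.set_index("gene_id")["label"])


def read_expression(path, groups_path) -> ExpressionSet:
    """Parse and validate an expression matrix plus its group map.

    Raises a distinct, messaged :class:`InputError` for a malformed header,
    a non-numeric cell, duplicate gene ids, samples missing from the group
    map, or a group map without exactly two groups.
    """
    head = pd.read_csv(path, sep="\t", nrows=0)
    if head.columns[0] != "gene_id" or len(head.columns) < 2:
        raise InputError(
            f"{path}: malformed header; first column must be 'gene_id' "
            "followed by at least one sample column"
        )
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        raise InputError(f"{path}: non-numeric cells in columns {non_numeric}")

    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(gdf.columns[:2]) != ["sample_id", "group"]:
        raise InputError(f"{groups_path}: expected columns sample_id, group")
    groups = gdf.set_index("sample_id")["group"]
    unknown = [s for s in groups.index if s not in df.columns]
    if unknown:
        raise InputError(f"{groups_path}: unknown samples {unknown}")
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise InputError(f"{groups_path}: samples missing a group: {missing}")
    n_groups = groups.nunique()
    if n_groups != 2:
        raise InputError(f"{groups_path}: expected exactly 2 groups, found {n_groups}")
    return ExpressionSet(df, groups)


def write_result(result, path) -> None:
    """Detection result as TSV: gene_id, statistic, p_value, fold_change,
    direction, detected (0/1), plus any method-specific extras."""
    table = result.table.copy()
    table["detected"] = table["detected"].astype(int)
    table.rename_axis("gene_id").to_csv(path, sep="\t", na_rep="")


def read_result_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    table["detected"] = table["detected"].astype(bool)
    return table


def read_simulation_config(path) -> SimulationConfig:
    """SimulationConfig from a YAML or JSON mapping with exact field names."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InputError(f"{path}: expected a mapping of config fields")
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise InputError(f"{path}: unknown config fields {sorted(unknown)}")
    config = SimulationConfig(**data)
    config.validate()
    return config
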