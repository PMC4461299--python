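"""Two-group expression simulator with a known answer key.

Each simulated gene carries i.i.d. normal values in a control and a
treatment group.  A fixed number of genes ("artificial DEGs", aDEGs) have
their treatment-group mean shifted up or down by a configurable amount with
a shared standard deviation; all remaining genes are null.  Values are on a
log-like scale (means around 10, sigma ~1.3, matching post-normalization
log2 intensities), so group-mean differences play the role of log fold
changes.

Two named presets reproduce the benchmark conditions:

``dataset1``
    2000 genes, 73 aDEGs, background N(10, 1.3^2), up-shifted genes at
    mean 15 and down-shifted at mean 5 — the three classes are essentially
    fully separated.
``dataset2``
    Same layout with subtler shifts (13.5 / 6.5), so the up-regulated class
    partially overlaps the upper tail of the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, ExpressionSet, GroundTruth


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-group dataset.

    The up/down split of the shifted genes defaults to 37 up + 36 down.
    ``n_samples_per_group`` defaults to 10 replicates per group.
    """

    n_genes: int = 2000
    n_up: int = 37
    n_down: int = 36
    background_mean: float = 10.0
    up_mean: float = 15.0
    down_mean: float = 5.0
    sigma: float = 1.3
    n_samples_per_group: int = 10
    seed: int = 0

    @property
    def n_adegs(self) -> int:
        return self.n_up + self.n_down

    def validate(self) -> None:
        if min(self.n_genes, self.n_up, self.n_down) < 0:
            raise ConfigurationError("gene counts must be non-negative")
        if self.n_adegs > self.n_genes:
            raise ConfigurationError(
                f"n_up + n_down = {self.n_adegs} exceeds n_genes = {self.n_genes}"
            )
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.n_samples_per_group < 1:
            raise ConfigurationError("need at least one sample per group")
        if self.n_up > 0 and not self.up_mean > self.background_mean:
            raise ConfigurationError("up_mean must exceed background_mean")
        if self.n_down > 0 and not self.down_mean < self.background_mean:
            raise ConfigurationError("down_mean must be below background_mean")


PRESETS: dict[str, SimulationConfig] = {
    "dataset1": SimulationConfig(up_mean=15.0, down_mean=5.0),
    "dataset2": SimulationConfig(up_mean=13.5, down_mean=6.5),
}


def preset(name: str, **overrides) -> SimulationConfig:
    """Return a named preset, optionally with fields overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return replace(base, **overrides)


def generate(config: SimulationConfig) -> tuple[ExpressionSet, GroundTruth]:
    """Draw one dataset and its answer key, deterministically from the seed.

    Control-group values of every gene are N(background_mean, sigma^2).
    Treatment-group values are N(background_mean, sigma^2) for null genes
    and N(up_mean / down_mean, sigma^2) for shifted genes.  Gene order is
    randomized so shifted genes are not clustered at the top of the matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, config.n_samples_per_group

    labels = np.array(
        ["up"] * config.n_up
        + ["down"] * config.n_down
        + ["none"] * (g - config.n_adegs)
    )
    rng.shuffle(labels)

    treat_means = np.full(g, config.background_mean)
    treat_means[labels == "up"] = config.up_mean
    treat_means[labels == "down"] = config.down_mean

    control = rng.normal(config.background_mean, config.sigma, size=(g, n))
    treatment = rng.normal(treat_means[:, None], config.sigma, size=(g, n))

    width = max(6, len(str(g)))
    gene_ids = pd.Index([f"g{i + 1:0{width}d}" for i in range(g)], name="gene_id")
    sample_ids = [f"ctrl_{j + 1:02d}" for j in range(n)] + [
        f"treat_{j + 1:02d}" for j in range(n)
    ]
    values = pd.DataFrame(
        np.hstack([control, treatment]), index=gene_ids, columns=sample_ids
    )
    groups = pd.Series(
        ["control"] * n + ["treatment"] * n, index=sample_ids, name="group"
    )
    truth = GroundTruth(pd.Series(labels, index=gene_ids, name="label"))
    return ExpressionSet(values, groups, control="control"), truth


_CLASS_NAMES = {"none": "other", "up": "up regulated", "down": "down regulated"}


def class_summary(expr: ExpressionSet, truth: GroundTruth) -> pd.DataFrame:
    """Five-number summaries of treatment-group values per truth class.

    Returns one row per non-empty class among {other, up regulated,
    down regulated} with columns min, q1, median, q3, max — the numbers a
    boxplot of the simulated classes would show.  Empty classes are omitted
    with a warning.
    """
    truth.check_matches(expr.gene_ids)
    treat = pd.DataFrame(
        expr.treatment_matrix(), index=expr.gene_ids
    )
    rows = {}
    for label, pretty in _CLASS_NAMES.items():
        vals = treat.loc[truth.label_of == label].to_numpy().ravel()
        if vals.size == 0:
            warnings.warn(f"class {pretty!r} is empty; omitted from summary")
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows[pretty] = {
            "min": vals.min(),
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": vals.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
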