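"""Six differential-expression detectors behind one interface.

Every detector maps an :class:`~degbench.datatypes.ExpressionSet` plus a
:class:`MethodParams` to a :class:`~degbench.datatypes.DetectionResult`
with one record per gene.  Use :func:`detect` to dispatch by method name.
"""

from __future__ import annotations

from ..datatypes import DetectionResult, ExpressionSet
from .base import (
    DEFAULT_ALPHA,
    DEFAULT_PERMUTATIONS,
    METHODS,
    MethodParams,
    fold_change,
)
from .moderated_t import detect_limma, estimate_prior
from .parametric import detect_ba, detect_mw, detect_tt
from .rankproduct import detect_rp
from .sam import choose_s0, detect_sam, relative_difference

_DISPATCH = {
    "SAM": detect_sam,
    "RP": detect_rp,
    "BA": detect_ba,
    "MW": detect_mw,
    "TT": detect_tt,
    "LIMMA": detect_limma,
}


def detect(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Run the detector named by ``params.method``."""
    return _DISPATCH[params.method](expr, params)


__all__ = [
    "METHODS",
    "DEFAULT_ALPHA",
    "DEFAULT_PERMUTATIONS",
    "MethodParams",
    "DetectionResult",
    "detect",
    "fold_change",
    "detect_sam",
    "detect_rp",
    "detect_ba",
    "detect_mw",
    "detect_tt",
    "detect_limma",
    "choose_s0",
    "relative_difference",
    "estimate_prior",
]
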