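"""Scalar clinical formulas and the balanced-resampling significance test.

Covers the study-level quantities that are plain arithmetic on measured
values: static lung compliance from a ventilator reading, relative gene
expression from qPCR cycle thresholds (ddCt), collagen mass normalized to
lung wet weight, and the balanced random-subsampling t-test used to compare
fibrosis scores between groups of unequal size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComplianceRecord",
    "CtQuad",
    "CollagenRecord",
    "ResampleTestResult",
    "static_compliance",
    "ddct",
    "collagen_per_weight",
    "balanced_resample_ttest",
    "DEFAULT_PEEP",
]

DEFAULT_PEEP = 2.0  # cm H2O, the protocol's ventilator setting


@dataclass(frozen=True)
class ComplianceRecord:
    """Tidal volume (mL) and pressures (cm H2O) from one ventilator run."""

    tidal_volume: float
    plateau_pressure: float
    peep: float = DEFAULT_PEEP

    def __post_init__(self) -> None:
        if self.tidal_volume < 0:
            raise ValueError("tidal_volume must be >= 0")


@dataclass(frozen=True)
class CtQuad:
    """The four qPCR cycle thresholds entering ddCt."""

    ct_control_ref: float
    ct_sample_ref: float
    ct_control_goi: float
    ct_sample_goi: float

    def __post_init__(self) -> None:
        for name in ("ct_control_ref", "ct_sample_ref", "ct_control_goi", "ct_sample_goi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")


@dataclass(frozen=True)
class CollagenRecord:
    """Sircol collagen mass (ug) and lung wet weight (mg) of one sample."""

    collagen_mass: float
    lung_wet_weight: float

    def __post_init__(self) -> None:
        if self.collagen_mass < 0:
            raise ValueError("collagen_mass must be >= 0")
        if self.lung_wet_weight <= 0:
            raise ValueError("lung_wet_weight must be > 0")


@dataclass
class ResampleTestResult:
    """Per-repeat sampled indices, t statistics and two-sided p values."""

    indices: list[np.ndarray]
    t_statistics: list[float]
    p_values: list[float]
    n_repeats: int
    seed: int | None
    equal_var: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": range(1, self.n_repeats + 1),
                "t": self.t_statistics,
                "p": self.p_values,
                "sampled_indices": [",".join(map(str, ix)) for ix in self.indices],
            }
        )


def static_compliance(rec: ComplianceRecord) -> float:
    """C_st = TV / (plateau pressure - PEEP), in mL per cm H2O."""
    dp = rec.plateau_pressure - rec.peep
    if dp <= 0:
        raise ValueError(
            f"plateau_pressure ({rec.plateau_pressure}) must exceed PEEP ({rec.peep}) "
            "for a defined static compliance"
        )
    return rec.tidal_volume / dp


def ddct(q: CtQuad, livak: bool = False) -> tuple[float, float]:
    """Comparative cycle-threshold quantity and its fold change.

    ddCt = (Ct_control(ref) - Ct_sample(ref)) - (Ct_control(goi) - Ct_sample(goi)).

    ``fold_change`` is 2**ddCt under this sign convention. Note that a
    sample expressing MORE of the gene of interest than the control (lower
    Ct_sample(goi)) yields a negative ddCt and a fold change below 1; pass
    ``livak=True`` for the common 2**(-ddCt) convention instead.
    """
    d = (q.ct_control_ref - q.ct_sample_ref) - (q.ct_control_goi - q.ct_sample_goi)
    fc = 2.0 ** (-d) if livak else 2.0 ** d
    return d, fc


def collagen_per_weight(rec: CollagenRecord) -> float:
    """Collagen mass normalized to lung wet weight (ug per mg)."""
    return rec.collagen_mass / rec.lung_wet_weight


def balanced_resample_ttest(
    scores_large,
    scores_small,
    n_repeats: int = 3,
    seed: int | None = None,
    equal_var: bool = True,
) -> ResampleTestResult:
    """Compare unequal groups by repeatedly subsampling the larger one.

    Each repeat draws ``len(scores_small)`` values without replacement from
    ``scores_large`` and runs a two-tailed unpaired t-test against
    ``scores_small`` (pooled variance by default, the classical Student's
    test; ``equal_var=False`` gives Welch). All repeats are reported; with
    equal group sizes every repeat uses the full large group, so t and p
    are identical across repeats.
    """
    large = np.asarray(scores_large, dtype=np.float64)
    small = np.asarray(scores_small, dtype=np.float64)
    if small.size < 2:
        raise ValueError("the smaller group must have at least 2 scores (t-test undefined)")
    if large.size < small.size:
        raise ValueError(
            f"scores_large (n={large.size}) must be at least as large as scores_small (n={small.size})"
        )
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    indices, ts, ps = [], [], []
    for _ in range(n_repeats):
        ix = np.sort(rng.choice(large.size, size=small.size, replace=False))
        t, p = stats.ttest_ind(large[ix], small, equal_var=equal_var)
        indices.append(ix)
        ts.append(float(t))
        ps.append(float(p))
    return ResampleTestResult(
        indices=indices,
        t_statistics=ts,
        p_values=ps,
        n_repeats=n_repeats,
        seed=seed,
        equal_var=equal_var,
    )
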