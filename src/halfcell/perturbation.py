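"""qPCR quantification and group tests for perturbation experiments.

Relative expression is quantified by the comparative-Ct method, 2^-dCt
against a spike-in or housekeeping reference. Group means are compared by
Welch's t-test (unequal variance, two-tailed). Group *variability* is
compared by a subsampling permutation test: repeatedly draw a fixed-size
subsample from each intact group, compute sample SDs, and report the
probability that the treated group's SD reaches the control group's — a
small p means the treatment reduced intercellular variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def relative_expression_2dct(ct_target: float, ct_reference: float):
    """Comparative-Ct relative level, 2^-(Ct_target - Ct_reference).

    Accepts scalars or arrays; log2 of the result is exactly -dCt.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_target)) and np.all(np.isfinite(ct_reference))):
        raise ValueError("Ct values must be finite")
    out = np.exp2(-(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out


def qpcr_relative_levels(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 2^-dCt levels from a (sample, group, ct_target,
    ct_reference) table; technical replicates of a sample are averaged on
    the Ct scale first."""
    required = {"sample", "group", "ct_target", "ct_reference"}
    if not required.issubset(table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    cts = table.groupby(["sample", "group"], as_index=False)[
        ["ct_target", "ct_reference"]
    ].mean()
    cts["relative_level"] = relative_expression_2dct(
        cts["ct_target"].to_numpy(), cts["ct_reference"].to_numpy()
    )
    return cts


def welch_t_test(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-tailed.

    Conventions for degenerate input: both groups constant and equal gives
    (0, 1); both constant but different gives (signed inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return float(np.sign(a[0] - b[0]) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class VarPermResult:
    """Outcome of the subsampling variance permutation test."""

    sd_control: float
    sd_treated: float
    p: float
    n_perm: int
    subsample: int
    per_size_p: dict[int, float] = field(default_factory=dict)


def variance_permutation_test(
    control,
    treated,
    subsample: int = 15,
    n_perm: int = 1000,
    seed: int = 0,
) -> VarPermResult:
    """Test whether the treated group is less variable than the control.

    Per iteration, ``subsample`` values are drawn without replacement
    independently from each intact group and sample SDs (n-1) compared;
    p = (# iterations with SD_treated >= SD_control) / n_perm. Invariant to
    shifting both groups by a constant or scaling both by a positive factor.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if subsample < 2:
        raise ValueError("subsample must be >= 2")
    for name, g in (("control", control), ("treated", treated)):
        if g.size < subsample:
            raise ValueError(
                f"subsample {subsample} exceeds {name} group size {g.size}"
            )
    rng = np.random.default_rng(seed)
    # Vectorized draws: random keys -> first `subsample` order positions.
    idx_c = np.argsort(rng.random((n_perm, control.size)), axis=1)[:, :subsample]
    idx_t = np.argsort(rng.random((n_perm, treated.size)), axis=1)[:, :subsample]
    sd_c = control[idx_c].std(axis=1, ddof=1)
    sd_t = treated[idx_t].std(axis=1, ddof=1)
    p = float(np.mean(sd_t >= sd_c))
    return VarPermResult(
        sd_control=float(control.std(ddof=1)),
        sd_treated=float(treated.std(ddof=1)),
        p=p,
        n_perm=n_perm,
        subsample=subsample,
    )


def robustness_scan(
    control,
    treated,
    sizes=range(13, 19),
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Repeat the variance permutation test over a range of subsample sizes.

    Each size uses an independent seed-derived RNG substream, so the map is
    reproducible and sizes can be compared without shared sampling noise.
    """
    sizes = sorted(int(s) for s in sizes)
    out: dict[int, float] = {}
    for size in sizes:
        res = variance_permutation_test(
            control, treated, subsample=size, n_perm=n_perm,
            seed=np.random.default_rng([int(seed), size]).integers(2**31),
        )
        out[size] = res.p
    return out
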