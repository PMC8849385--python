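"""Population-level statistics and small assay calculations.

Covers cell-length distributions with the >4 μm filamentous rule, Welch
two-sample t-tests under normal or lognormal families, phospho-ratio
normalization, turbidity blank subtraction, exponential growth-rate
estimation, and ionic-strength accounting for buffer compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "LengthDistribution",
    "TestResult",
    "IonSpecies",
    "BufferComposition",
    "RatioRecord",
    "binomial_interval",
    "length_stats",
    "two_sample_test",
    "normalized_ratio",
    "turbidity_blank_subtract",
    "growth_rate",
    "ionic_strength",
    "SPECIES_PRESETS",
]


def binomial_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% (by default) Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass
class LengthDistribution:
    lengths_um: np.ndarray
    median_um: float
    q1_um: float
    q3_um: float
    threshold_um: float
    filamentous_fraction: float
    ci_low: float
    ci_high: float
    n: int


def length_stats(lengths_um, threshold_um: float = 4.0) -> LengthDistribution:
    """Summarize a cell-length sample; "filamentous" means strictly > threshold."""
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length sample")
    if np.any(lengths <= 0):
        raise ValueError("cell lengths must be positive")
    n_fil = int(np.sum(lengths > threshold_um))
    lo, hi = binomial_interval(n_fil, lengths.size)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return LengthDistribution(
        lengths_um=lengths,
        median_um=float(med),
        q1_um=float(q1),
        q3_um=float(q3),
        threshold_um=threshold_um,
        filamentous_fraction=n_fil / lengths.size,
        ci_low=lo,
        ci_high=hi,
        n=lengths.size,
    )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    family: str
    n_a: int
    n_b: int
    equal_var: bool = False


def two_sample_test(
    a, b, family: str = "normal", equal_var: bool = False
) -> TestResult:
    """Two-sample t-test (Welch by default; pooled variance with
    ``equal_var=True``).

    The lognormal family applies the identical test to log-transformed
    values, which requires strictly positive data.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if family == "lognormal":
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("lognormal family requires strictly positive data")
        a, b = np.log(a), np.log(b)
    elif family != "normal":
        raise ValueError(f"unknown family {family!r}; use 'normal' or 'lognormal'")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        family=family,
        n_a=a.size,
        n_b=b.size,
        equal_var=equal_var,
    )


@dataclass
class RatioRecord:
    numerator: float
    denominator: float
    ref_numerator: float | None
    ref_denominator: float | None
    ratio: float


def normalized_ratio(
    num: float,
    den: float,
    ref_num: float | None = None,
    ref_den: float | None = None,
) -> RatioRecord:
    """Signal ratio ``num/den``, optionally normalized to a reference pair.

    Used for phospho-form quantification: the phosphorylated/total (or
    phosphorylated/unphosphorylated) band ratio divided by the same ratio in
    the reference (wild-type) sample.
    """
    if den <= 0:
        raise ValueError("denominator must be > 0")
    ratio = num / den
    if ref_num is not None or ref_den is not None:
        if ref_num is None or ref_den is None:
            raise ValueError("reference pair must be given together")
        if ref_den <= 0:
            raise ValueError("reference denominator must be > 0")
        ref_ratio = ref_num / ref_den
        if ref_ratio <= 0:
            raise ValueError("reference ratio must be > 0")
        ratio = ratio / ref_ratio
    return RatioRecord(num, den, ref_num, ref_den, float(ratio))


def turbidity_blank_subtract(absorbances, blank) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise blank subtraction for plate-reader absorbance tables.

    Returns ``(corrected, negative_flags)``; negative corrected values are
    retained (they carry information about blank drift) but flagged.
    """
    a = np.asarray(absorbances, dtype=float)
    b = np.asarray(blank, dtype=float)
    if b.ndim > 0 and b.shape != a.shape:
        raise ValueError(f"blank shape {b.shape} does not match values {a.shape}")
    corrected = a - b
    return corrected, corrected < 0


def growth_rate(
    t_h, od, window: tuple[int, int] | None = None, min_points: int = 4
) -> tuple[float, tuple[int, int]]:
    """Exponential growth rate (1/h) from an OD time series.

    Least-squares slope of ``ln(OD)`` versus time over either a user-set
    index window ``(start, stop)`` or the contiguous window (length >=
    ``min_points``) maximizing R².  A flat series returns rate 0.
    """
    t = np.asarray(t_h, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.size != od.size or t.size < min_points:
        raise ValueError(f"need >= {min_points} matched (t, od) points")
    if window is not None:
        lo, hi = window
        seg_t, seg_od = t[lo:hi], od[lo:hi]
        if np.any(seg_od <= 0):
            raise ValueError("non-positive OD inside the fit window")
        slope = _ln_slope(seg_t, seg_od)
        return slope, (lo, hi)

    if np.any(od <= 0):
        raise ValueError("non-positive OD values; set an explicit window")
    log_od = np.log(od)
    if np.ptp(log_od) == 0:
        return 0.0, (0, t.size)
    best = (-np.inf, 0.0, (0, t.size))
    for lo in range(0, t.size - min_points + 1):
        for hi in range(lo + min_points, t.size + 1):
            seg_t, seg_l = t[lo:hi], log_od[lo:hi]
            slope, intercept = np.polyfit(seg_t, seg_l, 1)
            pred = slope * seg_t + intercept
            ss_res = float(np.sum((seg_l - pred) ** 2))
            ss_tot = float(np.sum((seg_l - seg_l.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            # prefer larger windows among near-equal fits
            score = r2 + 1e-9 * (hi - lo)
            if score > best[0]:
                best = (score, slope, (lo, hi))
    return float(best[1]), best[2]


def _ln_slope(t: np.ndarray, od: np.ndarray) -> float:
    slope, _ = np.polyfit(t, np.log(od), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# ionic strength


@dataclass(frozen=True)
class IonSpecies:
    """One dissolved species: concentration in mM plus the ions it releases.

    ``ions`` lists ``(charge, stoichiometry)`` pairs for full dissociation;
    a species marked ``neglected`` (e.g. a zwitterionic buffer such as
    Hepes) contributes nothing.
    """

    name: str
    concentration_mM: float
    ions: tuple[tuple[int, int], ...] = ()
    neglected: bool = False

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise ValueError("concentration must be >= 0")
        if not self.neglected and not self.ions:
            raise ValueError(
                f"species {self.name!r}: charge specification missing "
                "(give ions or mark neglected)"
            )


SPECIES_PRESETS: dict[str, tuple[tuple[int, int], ...]] = {
    "KCl": ((+1, 1), (-1, 1)),
    "NaCl": ((+1, 1), (-1, 1)),
    "MgCl2": ((+2, 1), (-1, 2)),
    "CaCl2": ((+2, 1), (-1, 2)),
}


@dataclass
class BufferComposition:
    species: tuple[IonSpecies, ...]

    @classmethod
    def from_dict(cls, entries: dict[str, float | dict]) -> "BufferComposition":
        """Build from ``{name: mM}`` (presets / 'neglected') or full specs.

        A full spec is ``{name: {"mM": c, "ions": [[z, nu], ...]}}`` or
        ``{name: {"mM": c, "neglected": true}}``.
        """
        species = []
        for name, val in entries.items():
            if isinstance(val, dict):
                ions = tuple(tuple(i) for i in val.get("ions", ()))
                species.append(
                    IonSpecies(
                        name,
                        float(val["mM"]),
                        ions,
                        neglected=bool(val.get("neglected", False)),
                    )
                )
            elif name in SPECIES_PRESETS:
                species.append(IonSpecies(name, float(val), SPECIES_PRESETS[name]))
            elif name.lower() in ("hepes", "tris", "water", "h2o"):
                species.append(IonSpecies(name, float(val), neglected=True))
            else:
                raise ValueError(
                    f"species {name!r}: no charge preset; give an explicit spec"
                )
        return cls(tuple(species))


def ionic_strength(comp: BufferComposition) -> float:
    """Ionic strength ``I = ½ Σ c_i z_i²`` in mM over fully dissociated ions.

    Neglected (zwitterionic / partially ionized) species contribute zero.
    """
    total = 0.0
    for sp in comp.species:
        if sp.neglected:
            continue
        for charge, stoich in sp.ions:
            total += sp.concentration_mM * stoich * charge**2
    return 0.5 * total
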