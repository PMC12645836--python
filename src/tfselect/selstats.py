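"""Selection statistics: constraint ratios with bootstrap CIs, site-frequency
spectra, per-class alpha, the exponential asymptote fit, frequency-cutoff
selection, pooled traditional MK alpha, and the class-comparison tests.

Constraint ratios are normalized variant-count proportions: the density of test
(nonsynonymous, or binding-site) variants over their expected site length divided
by the density of neutral (synonymous) variants over theirs. Alpha is the MK
estimate of the proportion of adaptive substitutions,
``alpha = 1 - (Ds * Pn) / (Dn * Ps)``; the asymptotic variant fits per-frequency-
class alpha values to ``a + b * exp(-c * x)`` and reads the curve at x = 1, which
discounts segregating slightly deleterious variants concentrated in the low
frequency classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

DEFAULT_N_REPS = 500
DEFAULT_N_CLASSES = 50
DEFAULT_F_HIGH = 0.9


# ---------------------------------------------------------------------------
# constraint ratios
# ---------------------------------------------------------------------------

def constraint_ratio(test_count: float, test_sites: float, neutral_count: float, neutral_sites: float) -> float:
    """(test_count / test_sites) / (neutral_count / neutral_sites).

    Used both for polymorphism (pi_n/pi_s) and divergence (Kn/Ks) modes. For the
    TFBS mode the test site length is the total binding-site bp and the neutral
    class is the All-genes synonymous one.
    """
    if test_sites <= 0 or neutral_sites <= 0:
        raise ValueError("site lengths must be positive")
    if neutral_count <= 0:
        raise ValueError(
            "zero neutral variants: the ratio is undefined; pool more loci into the neutral class"
        )
    return (test_count / test_sites) / (neutral_count / neutral_sites)


@dataclass
class ConstraintEstimate:
    region_class: str
    mode: str  # "polymorphism" or "divergence"
    test_count: float
    test_sites: float
    neutral_count: float
    neutral_sites: float
    estimate: float
    replicates: np.ndarray | None = None
    ci: tuple | None = None


def bootstrap_ci(units, statistic, n_reps: int = DEFAULT_N_REPS, seed: int = 0, max_redraw: int = 100):
    """Nonparametric bootstrap over resampling units (genes or CRMs).

    ``statistic(resampled_units)`` is evaluated on each with-replacement resample;
    replicates where it raises or returns a non-finite value are redrawn (their
    count is reported). Returns (replicates, (lo, hi), n_redrawn) with a 2.5/97.5
    percentile interval.
    """
    units = list(units)
    if len(units) < 2:
        raise ValueError("need at least 2 resampling units")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    n_redrawn = 0
    for r in range(n_reps):
        for _ in range(max_redraw):
            pick = rng.integers(0, len(units), size=len(units))
            try:
                val = statistic([units[i] for i in pick])
            except (ValueError, ZeroDivisionError):
                n_redrawn += 1
                continue
            if np.isfinite(val):
                reps[r] = val
                break
            n_redrawn += 1
        else:
            raise ValueError("statistic undefined in every redraw of a bootstrap replicate")
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return reps, ci, n_redrawn


def constraint_ratio_bootstrap(
    unit_counts,
    region_class: str = "",
    mode: str = "polymorphism",
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> ConstraintEstimate:
    """Constraint ratio with a unit-level bootstrap CI.

    ``unit_counts`` is a sequence of per-unit tuples
    (test_count, test_sites, neutral_count, neutral_sites); totals are summed
    within each bootstrap resample before forming the ratio, so within-locus
    correlation is preserved.
    """
    arr = np.asarray(unit_counts, dtype=float)

    def stat(units):
        u = np.asarray(units, dtype=float)
        t, ts, n, ns = u.sum(axis=0)
        return constraint_ratio(t, ts, n, ns)

    t, ts, n, ns = arr.sum(axis=0)
    est = constraint_ratio(t, ts, n, ns)
    reps, ci, _ = bootstrap_ci([tuple(row) for row in arr], stat, n_reps=n_reps, seed=seed)
    return ConstraintEstimate(region_class, mode, t, ts, n, ns, est, reps, ci)


# ---------------------------------------------------------------------------
# SFS and alpha
# ---------------------------------------------------------------------------

@dataclass
class AlphaCurve:
    midpoints: np.ndarray
    alpha: np.ndarray  # NaN where the class is missing (ps == 0)
    pn: np.ndarray
    ps: np.ndarray
    Dn: float
    Ds: float


def build_sfs(frequencies, n_classes: int = DEFAULT_N_CLASSES) -> np.ndarray:
    """Bin derived-allele frequencies into equal-width classes over (0, 1).

    Bin edges are half-open with the top bin closed (numpy histogram convention);
    frequencies at 0 or 1 are rejected (those sites are not polymorphic).
    """
    f = np.asarray(list(frequencies), dtype=float)
    if f.size and ((f <= 0) | (f >= 1)).any():
        raise ValueError("frequencies must lie strictly in (0, 1)")
    counts, _ = np.histogram(f, bins=n_classes, range=(0.0, 1.0))
    return counts


def sfs_midpoints(n_classes: int = DEFAULT_N_CLASSES) -> np.ndarray:
    edges = np.linspace(0.0, 1.0, n_classes + 1)
    return (edges[:-1] + edges[1:]) / 2


def alpha_curve(pn, ps, Dn: float, Ds: float, midpoints=None) -> AlphaCurve:
    """Per-frequency-class alpha: alpha(x) = 1 - (Ds/Dn) * (pn(x)/ps(x)).

    Classes with ps(x) == 0 are flagged missing (NaN), never imputed.
    """
    pn = np.asarray(pn, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if Dn <= 0 or Ds <= 0:
        raise ValueError("alpha is undefined without both Dn > 0 and Ds > 0")
    if midpoints is None:
        midpoints = sfs_midpoints(len(pn))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 1.0 - (Ds / Dn) * (pn / ps)
    a[ps == 0] = np.nan
    return AlphaCurve(np.asarray(midpoints, dtype=float), a, pn, ps, float(Dn), float(Ds))


# ---------------------------------------------------------------------------
# asymptotic fit and cutoffs
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticFit:
    a: float
    b: float
    c: float
    asymptote: float  # fitted alpha at x = 1
    linear_fallback: bool = False
    ci: tuple | None = None
    n_classes_used: int = 0
    fit_range: tuple = (0.0, 1.0)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.linear_fallback:
            return self.a + self.b * x
        return self.a + self.b * np.exp(-self.c * x)


def _exp_model(x, a, b, c):
    return a + b * np.exp(-c * x)


def _fit_points(x, y, sigma=None):
    """Exponential fit with linear fallback; returns (a, b, c, fallback)."""
    try:
        p0 = (y[-1], (y[0] - y[-1]) / max(np.exp(-5 * x[0]), 1e-12) if x.size else -1.0, 5.0)
        popt, _ = optimize.curve_fit(
            _exp_model, x, y, p0=p0, sigma=sigma, maxfev=10000,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        )
        a, b, c = (float(v) for v in popt)
        if c <= 0 or not np.all(np.isfinite([a, b, c])):
            raise RuntimeError("non-convergent exponential")
        return a, b, c, False
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        weights = None if sigma is None else 1.0 / np.asarray(sigma) ** 2
        slope, intercept = np.polyfit(x, y, 1, w=weights)
        return float(intercept), float(slope), 0.0, True


def _alpha_class_sigma(curve: AlphaCurve, mask: np.ndarray) -> np.ndarray:
    """Approximate SE of per-class alpha by Poisson error propagation.

    var(alpha_k) ~ ((Ds/Dn)(pn/ps))^2 (1/pn + 1/ps + 1/Dn + 1/Ds); classes with
    more variants therefore anchor the fit. A small floor keeps zero-pn classes
    from receiving infinite weight.
    """
    pn = np.maximum(curve.pn[mask], 0.5)
    ps = np.maximum(curve.ps[mask], 0.5)
    ratio = (curve.Ds / curve.Dn) * (pn / ps)
    var = ratio**2 * (1 / pn + 1 / ps + 1 / curve.Dn + 1 / curve.Ds)
    return np.sqrt(np.maximum(var, 1e-4))


def fit_asymptote(
    curve: AlphaCurve,
    fit_range: tuple = (0.0, 1.0),
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    weighted: bool = False,
) -> AsymptoticFit:
    """Nonlinear least squares of a + b*exp(-c*x) to the non-missing classes.

    The asymptote is the fitted alpha at x = 1. With ``weighted=True`` classes
    are weighted by the inverse of their propagated Poisson variance. If the
    exponential fit fails or yields c <= 0, a linear fit is used and flagged.
    The CI on the asymptote comes from resampling the class points with
    replacement.
    """
    mask = (
        np.isfinite(curve.alpha)
        & (curve.midpoints >= fit_range[0])
        & (curve.midpoints <= fit_range[1])
    )
    x, y = curve.midpoints[mask], curve.alpha[mask]
    if x.size < 4:
        raise ValueError(f"need >= 4 usable frequency classes in {fit_range}, have {x.size}")
    sigma = _alpha_class_sigma(curve, mask) if weighted else None
    a, b, c, fallback = _fit_points(x, y, sigma)
    asym = a + b * (1.0 if fallback else np.exp(-c))

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_reps):
        pick = rng.integers(0, x.size, size=x.size)
        if np.unique(x[pick]).size < 4:
            continue
        ra, rb, rc, rf = _fit_points(x[pick], y[pick], None if sigma is None else sigma[pick])
        boot.append(ra + rb * (1.0 if rf else np.exp(-rc)))
    ci = (
        (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
        if len(boot) >= 20
        else None
    )
    return AsymptoticFit(a, b, c, float(asym), fallback, ci, int(x.size), tuple(fit_range))


@dataclass
class FrequencyCutoffs:
    f_low: float
    f_high: float = DEFAULT_F_HIGH


def select_cutoffs(
    fit: AsymptoticFit,
    curve: AlphaCurve,
    delta: float = 0.1,
    delta_abs: float = 0.05,
    f_high: float = DEFAULT_F_HIGH,
) -> FrequencyCutoffs:
    """Automated surrogate for visual convergence inspection.

    f_low is the smallest class midpoint at which the fitted curve is within
    ``delta`` times the fitted-curve range of the asymptote -- but never chases
    wiggles smaller than ``delta_abs`` in absolute alpha units, so near-flat
    curves converge at the first class, as a visual reading would. The high
    cutoff is fixed at 0.9 by default (mis-polarized variants accumulate above
    it). If no class qualifies, f_low falls back to the largest usable midpoint
    with a warning.
    """
    import warnings

    usable = np.isfinite(curve.alpha) & (curve.midpoints <= f_high)
    mids = curve.midpoints[usable]
    if mids.size == 0:
        raise ValueError("no usable frequency classes at or below f_high")
    fitted = fit.predict(mids)
    span = np.abs(fitted.max() - fitted.min())
    # chase structure only when the fit beats a flat curve beyond sampling
    # noise (chi-square improvement over the constant model, 2 extra df at 5%);
    # a curve that is flat to within noise has converged at the first class
    y = curve.alpha[usable]
    sigma = _alpha_class_sigma(curve, usable)
    wmean = np.sum(y / sigma**2) / np.sum(1.0 / sigma**2)
    chi2_const = float(np.sum(((y - wmean) / sigma) ** 2))
    chi2_fit = float(np.sum(((y - fitted) / sigma) ** 2))
    if span <= 1e-12 or chi2_const - chi2_fit < 5.99:
        return FrequencyCutoffs(float(mids[0]), f_high)
    # converged exponential fits are compared against their limit a, so the
    # stabilization point is x = ln(|b| / (delta * span)) / c in closed form
    limit = fit.asymptote if fit.linear_fallback else fit.a
    ok = np.abs(fitted - limit) <= max(delta * span, delta_abs)
    if not ok.any():
        warnings.warn(
            "no frequency class within delta of the asymptote; using the largest usable midpoint",
            stacklevel=2,
        )
        return FrequencyCutoffs(float(mids[-1]), f_high)
    return FrequencyCutoffs(float(mids[ok][0]), f_high)


# ---------------------------------------------------------------------------
# pooled traditional MK alpha
# ---------------------------------------------------------------------------

def mk_alpha(Pn: float, Ps: float, Dn: float, Ds: float) -> float:
    if Ps <= 0 or Dn <= 0:
        raise ValueError("alpha undefined: requires Ps > 0 and Dn > 0")
    return 1.0 - (Ds * Pn) / (Dn * Ps)


@dataclass
class PooledMKResult:
    alpha: float
    ci: tuple | None
    Pn: int
    Ps: int
    Dn: float
    Ds: float
    cutoffs: FrequencyCutoffs
    replicates: np.ndarray | None = None


def pooled_mk_alpha(
    nonsyn_freqs,
    syn_freqs,
    Dn: float,
    Ds: float,
    cutoffs: FrequencyCutoffs | None = None,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    resample_divergence: bool = False,
) -> PooledMKResult:
    """Traditional MK alpha on polymorphisms pooled within frequency cutoffs.

    Polymorphisms with f_low <= frequency <= f_high are retained; divergence
    counts are used as given. The CI comes from ``n_reps`` resampling cycles of
    the retained polymorphism data (divergence held fixed); with
    ``resample_divergence=True`` the divergence counts are additionally
    resampled as Poisson draws, giving the CI frequentist coverage when
    divergence noise is not negligible next to polymorphism noise.
    """
    if cutoffs is None:
        cutoffs = FrequencyCutoffs(0.0)
    fn = np.asarray(list(nonsyn_freqs), dtype=float)
    fs = np.asarray(list(syn_freqs), dtype=float)
    fn = fn[(fn >= cutoffs.f_low) & (fn <= cutoffs.f_high)]
    fs = fs[(fs >= cutoffs.f_low) & (fs <= cutoffs.f_high)]
    Pn, Ps = len(fn), len(fs)
    alpha = mk_alpha(Pn, Ps, Dn, Ds)

    rng = np.random.default_rng(seed)
    total = Pn + Ps
    reps = []
    attempts = 0
    while len(reps) < n_reps and attempts < 20 * n_reps:
        attempts += 1
        k = rng.binomial(total, Pn / total) if total else 0
        if total - k <= 0:
            continue
        if resample_divergence:
            dn_r, ds_r = rng.poisson(Dn), rng.poisson(Ds)
            if dn_r == 0:
                continue
        else:
            dn_r, ds_r = Dn, Ds
        reps.append(1.0 - (ds_r * k) / (dn_r * (total - k)))
    reps = np.asarray(reps)
    ci = (
        (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
        if reps.size >= 20
        else None
    )
    return PooledMKResult(float(alpha), ci, Pn, Ps, float(Dn), float(Ds), cutoffs, reps)


# ---------------------------------------------------------------------------
# class-comparison tests
# ---------------------------------------------------------------------------

def compare_classes_welch(replicates_a, replicates_b):
    """Two-sided Welch's t-test on bootstrap replicate distributions.

    Mirrors the published procedure of testing resampled constraint-ratio
    distributions; note such p-values understate uncertainty because replicates
    are not independent observations. Zero variance in both with equal means is
    reported as the degenerate exact-equality case (t = 0, p = 1).
    """
    a = np.asarray(list(replicates_a), dtype=float)
    b = np.asarray(list(replicates_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per class")
    if a.std() == 0 and b.std() == 0:
        equal = float(a.mean()) == float(b.mean())
        return (0.0, 1.0) if equal else (np.inf * np.sign(a.mean() - b.mean()), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pathogenic_enrichment(pathogenic_bd: int, benign_bd: int, pathogenic_nonbd: int, benign_nonbd: int):
    """2x2 two-sided Fisher's exact test of pathogenic-variant enrichment.

    Returns (odds_ratio, p_value, proportion_bd, proportion_nonbd) where the
    proportions are pathogenic / (pathogenic + benign) per class. A zero margin
    gives p = 1 by convention.
    """
    table = np.array([[pathogenic_bd, benign_bd], [pathogenic_nonbd, benign_nonbd]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        odds = np.nan
        p = 1.0
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    prop_bd = pathogenic_bd / (pathogenic_bd + benign_bd) if pathogenic_bd + benign_bd else np.nan
    prop_nonbd = (
        pathogenic_nonbd / (pathogenic_nonbd + benign_nonbd)
        if pathogenic_nonbd + benign_nonbd
        else np.nan
    )
    return float(odds), float(p), prop_bd, prop_nonbd
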