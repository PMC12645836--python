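"""Forward Wright-Fisher simulation of a coding region under purifying selection,
recombination, and partial self-fertilization.

Each generation every offspring is produced by self-fertilization with
probability ``selfing_s`` (one parent contributes both gametes), otherwise by two
distinct parents sampled with probability proportional to fitness. Fitness is
multiplicative across sites with semidominance (h = 0.5): a nonsynonymous derived
allele carries coefficient ``s = two_Ns / (2N)``; synonymous sites are neutral.
Gametes recombine at per-bp rate ``rec``; new mutations arrive as
Poisson(mu * 2N * region_len) per generation at uniformly drawn positions and are
classified synonymous/nonsynonymous against the reference coding sequence.

After ``burnin`` generations (default 10N) the population is cloned into an
ingroup and an outgroup that evolve independently for ``generations`` more
generations. Divergence counts substitutions fixed on exactly one branch after
the split, excluding sites still polymorphic in the ingroup; both-branch
fixations of shared ancestral polymorphism cancel. The site-frequency spectra
come from one sampled haplotype per each of ``sample_n`` distinct individuals.

The standard rescaling practice applies: reduce N while holding 2Ns, 4Nmu and
4Nrec (and, ideally, total genomic mutational flux mu * region_len) constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codonsites, selstats

BASES = "ACGT"


@dataclass
class SimConfig:
    N: int = 50  # diploid individuals (rescaled)
    selfing_s: float = 0.0
    mu: float = 2e-5  # per bp per generation (rescaled)
    rec: float = 4e-5  # per bp per generation (rescaled)
    two_Ns: float = 9.0  # scaled coefficient against nonsynonymous mutations
    region_len: int = 99999
    generations: int = 1000  # per-branch generations after the split
    burnin: int | None = None  # default 10N
    sample_n: int = 20
    seed: int = 0
    # selfing evolved recently in the focal lineage: the burn-in (shared
    # ancestry) and the outgroup branch mate at this rate, the ingroup branch
    # at selfing_s. The default 0.0 mirrors an outcrossing outgroup.
    ancestral_selfing_s: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.selfing_s <= 1.0:
            raise ValueError(f"selfing_s must lie in [0, 1], got {self.selfing_s}")
        if not 0.0 <= self.ancestral_selfing_s <= 1.0:
            raise ValueError(
                f"ancestral_selfing_s must lie in [0, 1], got {self.ancestral_selfing_s}"
            )
        if self.region_len % 3 != 0:
            raise ValueError("region_len must be a multiple of 3")
        if self.two_Ns < 0:
            raise ValueError("two_Ns must be >= 0 in the purifying mode")
        if self.sample_n > 2 * self.N:
            raise ValueError("sample_n exceeds the number of haplotypes 2N")
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @property
    def burnin_gens(self) -> int:
        return 10 * self.N if self.burnin is None else self.burnin


@dataclass
class SimOutput:
    sfs_nonsyn: np.ndarray  # counts per derived-copy class 1..sample_n-1
    sfs_syn: np.ndarray
    Dn: int
    Ds: int
    diversity: float  # realized per-site pairwise diversity of the sample
    sample_n: int
    config: SimConfig
    L_syn: float = 0.0
    L_nonsyn: float = 0.0
    haplotypes: np.ndarray | None = None
    positions: np.ndarray | None = None
    alt_bases: np.ndarray | None = None  # derived base per segregating column
    reference_cds: str | None = None
    # time-averaged spectra: samples taken every N generations after the split
    # (partially correlated snapshots; per-class noise shrinks severalfold)
    sfs_nonsyn_acc: np.ndarray | None = None
    sfs_syn_acc: np.ndarray | None = None
    n_snapshots: int = 0


class ExtinctionError(RuntimeError):
    pass


class _Pop:
    """Haplotype matrix plus per-column mutation metadata."""

    __slots__ = ("G", "pos", "nonsyn", "ids", "alts")

    def __init__(self, n_hap: int):
        self.G = np.zeros((n_hap, 0), dtype=np.uint8)
        self.pos = np.zeros(0, dtype=np.int64)
        self.nonsyn = np.zeros(0, dtype=bool)
        self.ids = np.zeros(0, dtype=np.int64)
        self.alts = np.zeros(0, dtype=np.int8)  # index into the 3 non-reference bases

    def clone(self) -> "_Pop":
        p = _Pop(self.G.shape[0])
        p.G = self.G.copy()
        p.pos = self.pos.copy()
        p.nonsyn = self.nonsyn.copy()
        p.ids = self.ids.copy()
        p.alts = self.alts.copy()
        return p


def _reference_tables(rng: np.random.Generator, region_len: int):
    """Random stop-free coding sequence and a (L, 3) nonsynonymous lookup.

    Entry [p, j] tells whether the j-th alternative base (the three non-reference
    bases in ACGT order) at position p changes the encoded amino acid.
    """
    sense = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if codonsites.translate_codon(a + b + c) != "*"
    ]
    codons = rng.choice(sense, size=region_len // 3)
    cds = "".join(codons)
    lookup = codonsites.nonsyn_lookup(cds)
    table = np.zeros((region_len, 3), dtype=bool)
    for p, entry in enumerate(lookup):
        for j, (alt, is_ns) in enumerate(sorted(entry.items())):
            table[p, j] = is_ns
    counts = codonsites.ng_site_counts(cds)
    return cds, table, counts


def _fitness(pop: _Pop, s: float) -> np.ndarray:
    n_ind = pop.G.shape[0] // 2
    if s == 0.0 or not pop.nonsyn.any():
        return np.ones(n_ind)
    Gn = pop.G[:, pop.nonsyn]
    dosage = Gn[0::2].astype(np.int32) + Gn[1::2]
    n_het = (dosage == 1).sum(axis=1)
    n_hom = (dosage == 2).sum(axis=1)
    logw = n_het * np.log1p(-0.5 * s) + n_hom * np.log1p(-s)
    w = np.exp(logw - logw.max())
    return w


def _next_generation(pop: _Pop, cfg: SimConfig, rng: np.random.Generator, mut_id_start: int):
    N = cfg.N
    n_hap = 2 * N
    s = cfg.two_Ns / n_hap
    w = _fitness(pop, s)
    total_w = w.sum()
    if total_w <= 0 or not np.isfinite(total_w):
        raise ExtinctionError("population fitness collapsed to zero")
    p = w / total_w

    parents1 = rng.choice(N, size=N, p=p)
    parents2 = rng.choice(N, size=N, p=p)
    selfed = rng.random(N) < cfg.selfing_s
    parents2[selfed] = parents1[selfed]
    clash = (~selfed) & (parents1 == parents2)
    for _ in range(100):
        if not clash.any():
            break
        parents2[clash] = rng.choice(N, size=int(clash.sum()), p=p)
        clash = (~selfed) & (parents1 == parents2)

    # gamete g (row g of the offspring matrix) comes from parent P[g]
    P = np.empty(n_hap, dtype=np.int64)
    P[0::2] = parents1
    P[1::2] = parents2

    S = pop.G.shape[1]
    if S:
        base_h = rng.integers(0, 2, size=n_hap).astype(np.int8)
        n_cross = rng.poisson(cfg.rec * cfg.region_len, size=n_hap)
        total = int(n_cross.sum())
        switch = np.zeros((n_hap, S), dtype=np.int8)
        if total:
            g_ids = np.repeat(np.arange(n_hap), n_cross)
            breaks = rng.integers(1, cfg.region_len, size=total)
            col = np.searchsorted(pop.pos, breaks)
            inside = col < S
            np.add.at(switch, (g_ids[inside], col[inside]), 1)
        parity = np.cumsum(switch, axis=1, dtype=np.int8)
        parity += base_h[:, None]
        parity &= 1
        newG = pop.G[2 * P]  # fancy indexing copies; mix in the other haplotype in place
        use_b = parity.view(np.bool_)
        newG[use_b] = pop.G[2 * P + 1][use_b]
    else:
        newG = np.zeros((n_hap, 0), dtype=np.uint8)

    new = _Pop(n_hap)
    new.G = newG
    new.pos = pop.pos
    new.nonsyn = pop.nonsyn
    new.ids = pop.ids
    new.alts = pop.alts
    return new, mut_id_start


def _mutate(pop: _Pop, cfg: SimConfig, rng: np.random.Generator, nonsyn_table: np.ndarray, next_id: int) -> int:
    lam = cfg.mu * pop.G.shape[0] * cfg.region_len
    m = rng.poisson(lam)
    if m == 0:
        return next_id
    mpos = rng.integers(0, cfg.region_len, size=m)
    fresh = ~np.isin(mpos, pop.pos)
    mpos = mpos[fresh]
    _, first = np.unique(mpos, return_index=True)
    mpos = mpos[np.sort(first)]
    m = len(mpos)
    if m == 0:
        return next_id
    alt_j = rng.integers(0, 3, size=m)
    is_ns = nonsyn_table[mpos, alt_j]
    rows = rng.integers(0, pop.G.shape[0], size=m)
    cols = np.zeros((pop.G.shape[0], m), dtype=np.uint8)
    cols[rows, np.arange(m)] = 1
    pos = np.concatenate([pop.pos, mpos])
    order = np.argsort(pos, kind="stable")
    pop.G = np.concatenate([pop.G, cols], axis=1)[:, order]
    pop.pos = pos[order]
    pop.nonsyn = np.concatenate([pop.nonsyn, is_ns])[order]
    pop.ids = np.concatenate([pop.ids, np.arange(next_id, next_id + m)])[order]
    pop.alts = np.concatenate([pop.alts, alt_j.astype(np.int8)])[order]
    return next_id + m


def _purge(pop: _Pop, fixed_sink: dict | None = None) -> None:
    """Drop lost and fixed columns; optionally record fixed mutation ids."""
    colsum = pop.G.sum(axis=0)
    n_hap = pop.G.shape[0]
    fixed = colsum == n_hap
    if fixed_sink is not None and fixed.any():
        for mid, ns in zip(pop.ids[fixed], pop.nonsyn[fixed]):
            fixed_sink[int(mid)] = bool(ns)
    keep = (colsum > 0) & ~fixed
    if not keep.all():
        pop.G = pop.G[:, keep]
        pop.pos = pop.pos[keep]
        pop.nonsyn = pop.nonsyn[keep]
        pop.ids = pop.ids[keep]
        pop.alts = pop.alts[keep]


def _sample_sfs(pop: _Pop, cfg: SimConfig, rng) -> tuple:
    individuals = rng.choice(cfg.N, size=cfg.sample_n, replace=False)
    rows = 2 * individuals + rng.integers(0, 2, size=cfg.sample_n)
    k = pop.G[rows].sum(axis=0).astype(int)
    seg = (k > 0) & (k < cfg.sample_n)
    n = cfg.sample_n
    syn = np.bincount(k[seg & ~pop.nonsyn], minlength=n)[1:n]
    nonsyn = np.bincount(k[seg & pop.nonsyn], minlength=n)[1:n]
    return nonsyn, syn, k, seg, rows


def _evolve(
    pop: _Pop, cfg: SimConfig, rng, nonsyn_table, gens: int, next_id: int,
    fixed_sink=None, snapshot_sink=None, snapshot_every: int = 0,
) -> int:
    for g in range(gens):
        pop2, _ = _next_generation(pop, cfg, rng, next_id)
        pop.G, pop.pos, pop.nonsyn, pop.ids = pop2.G, pop2.pos, pop2.nonsyn, pop2.ids
        next_id = _mutate(pop, cfg, rng, nonsyn_table, next_id)
        _purge(pop, fixed_sink)
        if snapshot_sink is not None and snapshot_every and (g + 1) % snapshot_every == 0:
            nonsyn, syn, _, _, _ = _sample_sfs(pop, cfg, rng)
            snapshot_sink[0] += nonsyn
            snapshot_sink[1] += syn
            snapshot_sink[2] += 1
    return next_id


def run_simulation(config: SimConfig, keep_haplotypes: bool = False) -> SimOutput:
    """Burn in, split ingroup/outgroup, evolve both, sample SFS and divergence."""
    from dataclasses import replace

    rng = np.random.default_rng(config.seed)
    cds, nonsyn_table, site_counts = _reference_tables(rng, config.region_len)

    ancestral = replace(config, selfing_s=config.ancestral_selfing_s)
    pop = _Pop(2 * config.N)
    next_id = _evolve(pop, ancestral, rng, nonsyn_table, config.burnin_gens, 0, fixed_sink=None)

    fixed_in: dict = {}
    fixed_out: dict = {}
    n = config.sample_n
    snapshots = [np.zeros(n - 1), np.zeros(n - 1), 0]
    if config.generations > 0:
        out_pop = pop.clone()
        out_rng = np.random.default_rng(rng.integers(0, 2**31))
        next_id = _evolve(
            pop, config, rng, nonsyn_table, config.generations, next_id, fixed_in,
            snapshot_sink=snapshots, snapshot_every=config.N,
        )
        # outgroup mutations get ids from a disjoint range; the outgroup
        # lineage keeps the ancestral mating system
        _evolve(
            out_pop, ancestral, out_rng, nonsyn_table, config.generations,
            10**9 + next_id, fixed_out,
        )

    # final sample: one haplotype from each of sample_n distinct individuals
    sfs_nonsyn, sfs_syn, k, seg, hap_rows = _sample_sfs(pop, config, rng)

    # divergence: fixed on exactly one branch, not polymorphic in the ingroup
    segregating_ids = set(pop.ids[(pop.G.sum(axis=0) > 0)].tolist())
    diff_ids = set(fixed_in) ^ set(fixed_out)
    Dn = Ds = 0
    for mid in diff_ids:
        if mid in segregating_ids:
            continue
        ns = fixed_in.get(mid, fixed_out.get(mid))
        if ns:
            Dn += 1
        else:
            Ds += 1

    ksel = k[seg]
    diversity = float((2 * ksel * (n - ksel) / (n * (n - 1))).sum() / config.region_len)
    return SimOutput(
        sfs_nonsyn=sfs_nonsyn,
        sfs_syn=sfs_syn,
        Dn=Dn,
        Ds=Ds,
        diversity=diversity,
        sample_n=n,
        config=config,
        L_syn=site_counts.L_syn,
        L_nonsyn=site_counts.L_nonsyn,
        haplotypes=pop.G[hap_rows] if keep_haplotypes else None,
        positions=pop.pos.copy() if keep_haplotypes else None,
        alt_bases=_alt_bases(cds, pop) if keep_haplotypes else None,
        reference_cds=cds if keep_haplotypes else None,
        sfs_nonsyn_acc=snapshots[0] + sfs_nonsyn,
        sfs_syn_acc=snapshots[1] + sfs_syn,
        n_snapshots=snapshots[2] + 1,
    )


def _alt_bases(cds: str, pop: _Pop) -> np.ndarray:
    out = np.empty(len(pop.pos), dtype="U1")
    for i, (p, j) in enumerate(zip(pop.pos, pop.alts)):
        others = [b for b in BASES if b != cds[p]]
        out[i] = others[j]
    return out


def alpha_curve_from_sim(output: SimOutput, n_classes: int | None = None) -> selstats.AlphaCurve:
    """Per-frequency-class alpha from simulated polymorphism and divergence.

    Classes are derived-copy counts 1..sample_n-1, optionally re-binned into
    ``n_classes`` equal-width frequency bins. Requires Dn > 0 and Ds > 0.
    """
    if output.Dn <= 0 or output.Ds <= 0:
        raise ValueError("alpha curve undefined: needs Dn > 0 and Ds > 0")
    n = output.sample_n
    if n_classes is None:
        mids = np.arange(1, n) / n
        return selstats.alpha_curve(output.sfs_nonsyn, output.sfs_syn, output.Dn, output.Ds, mids)
    edges = np.linspace(0.0, 1.0, n_classes + 1)
    f = np.arange(1, n) / n
    which = np.clip(np.digitize(f, edges) - 1, 0, n_classes - 1)
    pn = np.bincount(which, weights=output.sfs_nonsyn, minlength=n_classes)
    ps = np.bincount(which, weights=output.sfs_syn, minlength=n_classes)
    return selstats.alpha_curve(pn, ps, output.Dn, output.Ds, selstats.sfs_midpoints(n_classes))


# ---------------------------------------------------------------------------
# selfing-regime study
# ---------------------------------------------------------------------------

SELFING_REGIMES = (0.0, 0.3, 0.6, 0.97)


@dataclass
class RegimeResult:
    selfing_s: float
    outputs: list = field(default_factory=list)
    curve: selstats.AlphaCurve | None = None
    fit: selstats.AsymptoticFit | None = None
    convergence_freq: float = np.nan
    convergence_jackknife: np.ndarray | None = None
    # full-spectrum fit: simulated data carry no polarization error, so the
    # asymptote is read from a fit over every frequency class
    full_fit: selstats.AsymptoticFit | None = None
    frequency_elevation: float = np.nan


def pooled_curve(outputs, n_classes: int | None = None, time_averaged: bool = True) -> selstats.AlphaCurve:
    """Alpha curve from replicate-pooled SFS and divergence counts.

    Pooling replicates emulates one long simulated region; by default the
    time-averaged spectra (snapshots every N generations) are pooled, which
    multiplies per-class counts severalfold. ``time_averaged=False`` uses the
    single end-point sample per replicate. Optional re-binning into
    ``n_classes`` frequency bins tames sparse high classes.
    """
    use_acc = time_averaged and all(o.sfs_nonsyn_acc is not None for o in outputs)
    if use_acc:
        sfs_n = np.sum([o.sfs_nonsyn_acc for o in outputs], axis=0)
        sfs_s = np.sum([o.sfs_syn_acc for o in outputs], axis=0)
    else:
        sfs_n = np.sum([o.sfs_nonsyn for o in outputs], axis=0)
        sfs_s = np.sum([o.sfs_syn for o in outputs], axis=0)
    Dn = sum(o.Dn for o in outputs)
    Ds = sum(o.Ds for o in outputs)
    if Dn <= 0 or Ds <= 0:
        raise ValueError("pooled alpha curve undefined: needs Dn > 0 and Ds > 0")
    n = outputs[0].sample_n
    if n_classes is None:
        return selstats.alpha_curve(sfs_n, sfs_s, Dn, Ds, np.arange(1, n) / n)
    edges = np.linspace(0.0, 1.0, n_classes + 1)
    f = np.arange(1, n) / n
    which = np.clip(np.digitize(f, edges) - 1, 0, n_classes - 1)
    pn = np.bincount(which, weights=sfs_n, minlength=n_classes)
    ps = np.bincount(which, weights=sfs_s, minlength=n_classes)
    return selstats.alpha_curve(pn, ps, Dn, Ds, selstats.sfs_midpoints(n_classes))


DEFAULT_REGIME_CLASSES = 10


def _excess_quantile(curve: selstats.AlphaCurve, delta: float) -> float:
    """Frequency by which alpha has converged on zero up to a delta remainder.

    Per class, alpha(x) = 0 exactly when pn(x)/ps(x) equals the divergence
    composition Dn/Ds, so the segregating deleterious excess in class x is
    pn(x) - (Dn/Ds) ps(x) -- which is the alpha deficit below zero weighted by
    ps(x). The convergence frequency is the (1 - delta) quantile of this excess
    mass: above it, at most a delta-fraction of the deleterious excess remains
    and the curve sits at its neutral expectation. Quantiles of pooled counts
    are far more stable than threshold crossings of fitted curves.
    """
    x, pn, ps = curve.midpoints, curve.pn, curve.ps
    excess = np.maximum(pn - (curve.Dn / curve.Ds) * ps, 0.0)
    total = excess.sum()
    if total <= 0:
        return float(x[0])
    cum = np.cumsum(excess) / total
    return float(x[np.argmax(cum >= 1.0 - delta)])


def _fit_convergence(curve: selstats.AlphaCurve, delta: float, f_high: float) -> float:
    fit = selstats.fit_asymptote(curve, fit_range=(0.0, f_high), n_reps=0)
    return selstats.select_cutoffs(fit, curve, delta=delta, f_high=f_high).f_low


def convergence_frequency(
    outputs,
    delta: float = 0.1,
    f_high: float = selstats.DEFAULT_F_HIGH,
    n_classes: int | None = None,
):
    """Alpha-convergence frequency of a replicate set, with jackknife spread.

    The replicate-pooled (time-averaged) curve is fitted with the exponential
    asymptote model and the convergence point is the first class whose fitted
    alpha sits within ``delta`` of the plateau; the replicate-level uncertainty
    comes from delete-one jackknife over replicates.
    """
    curve = pooled_curve(outputs, n_classes)
    f_conv = _fit_convergence(curve, delta, f_high)
    jack = []
    if len(outputs) > 2:
        for i in range(len(outputs)):
            sub = outputs[:i] + outputs[i + 1 :]
            try:
                jack.append(_fit_convergence(pooled_curve(sub, n_classes), delta, f_high))
            except ValueError:
                continue
    return f_conv, np.asarray(jack), curve


def frequency_elevation(outputs) -> float:
    """Mean derived frequency of nonsynonymous vs synonymous variants.

    The direct footprint of selective interference: linked selection under
    reduced effective recombination lets mildly deleterious variants drift to
    higher frequencies, raising this ratio toward 1.
    """
    curve = pooled_curve(outputs)
    x = curve.midpoints
    return float(((curve.pn * x).sum() / curve.pn.sum()) / ((curve.ps * x).sum() / curve.ps.sum()))


def selfing_study(
    base_config: SimConfig,
    regimes=SELFING_REGIMES,
    n_replicates: int = 10,
    delta: float = 0.1,
    seed: int = 0,
) -> list:
    """Run the four-regime experiment: replicate simulations per selfing rate,
    replicate-pooled alpha curves, and regime-level convergence frequencies."""
    results = []
    for r_idx, s_rate in enumerate(regimes):
        reg = RegimeResult(selfing_s=s_rate)
        for rep in range(n_replicates):
            cfg = SimConfig(
                N=base_config.N,
                selfing_s=s_rate,
                mu=base_config.mu,
                rec=base_config.rec,
                two_Ns=base_config.two_Ns,
                region_len=base_config.region_len,
                generations=base_config.generations,
                burnin=base_config.burnin,
                sample_n=base_config.sample_n,
                seed=seed + 1000 * r_idx + rep,
            )
            reg.outputs.append(run_simulation(cfg))
        try:
            f_conv, jack, curve = convergence_frequency(reg.outputs, delta=delta)
            reg.curve = curve
            reg.convergence_freq = float(np.mean(jack)) if jack.size else float(f_conv)
            reg.convergence_jackknife = jack
        except ValueError:  # no divergence at extreme reduced scale
            reg.convergence_jackknife = np.empty(0)
        if reg.curve is not None:
            try:
                reg.full_fit = selstats.fit_asymptote(
                    reg.curve, fit_range=(0.0, 1.0), n_reps=0, seed=seed
                )
                reg.fit = reg.full_fit
            except ValueError:
                reg.full_fit = None
        try:
            reg.frequency_elevation = frequency_elevation(reg.outputs)
        except (ValueError, ZeroDivisionError):
            pass
        results.append(reg)
    return results
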