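"""Self-contained genome + population + annotation fixtures.

The generator emulates the data scheme of a single-population resequencing study
of transcription-factor genes: codon-structured genes on one contig, a subset
flagged as TFs carrying a binding-domain (BD) interval, noncoding flanks hosting
scored cis-regulatory modules (CRMs) with planted motif instances, population
haplotypes segregating a controllable mixture of neutral / deleterious /
beneficial variants, an outgroup contig with Poisson divergence (reduced at
constrained sites), and synthetic benign/pathogenic labels with a configurable
BD enrichment.

Polymorphism is drawn from the stationary diffusion site-frequency spectrum:
for scaled coefficient gamma = 2Ns, the density of derived alleles at population
frequency q is proportional to

    H(gamma, q) = (1 - exp(-gamma (1 - q))) / ((1 - exp(-gamma)) q (1 - q))

which reduces to the neutral 1/q as gamma -> 0. Sample-frequency class
expectations are theta * integral(H * Binom(n, k, q) dq) per site. Divergence at
constrained sites is thinned by the relative fixation probability
u(gamma) = gamma / (1 - exp(-gamma)). All randomness flows from one seed;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codonsites
from .motifscan import PWM, pwm_from_counts
from .regions import (
    ALLGENES,
    BD,
    CRM,
    NONBD,
    TFBS,
    GenomicInterval,
    RegionCatalog,
    TranscriptModel,
    complement_domains,
    filter_crms,
)

BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if codonsites.translate_codon(a + b + c) != "*"
]

CONTIG = "chr1"


@dataclass
class FixtureConfig:
    """Generator settings; defaults emulate a small selfing-plant-like population.

    ``theta_per_site`` (0.005) and ``divergence_per_site`` (0.05) are typical
    thale-cress-scale values; ``sample_size`` follows the 45-haplotype population
    samples of the study design. ``sel_mix`` gives the (neutral, deleterious,
    beneficial) fractions of nonsynonymous mutations with scaled coefficients
    ``sel_coeffs`` (2Ns); the deleterious default 2Ns = -9 matches the purifying
    strength of the simulation study, and the beneficial class is rare and
    strong (2Ns = +100), per the MK framework's premise that adaptive
    mutations sweep quickly and contribute divergence but little polymorphism.
    """

    seed: int = 0
    n_genes: int = 30
    codons_per_gene: int = 200
    n_tf_genes: int = 10
    bd_fraction: float = 0.3
    flank_len: int = 3000
    n_crms: int = 20
    crm_score_range: tuple = (5, 60)
    motifs_per_crm: int = 2
    sample_size: int = 45
    theta_per_site: float = 0.005
    divergence_per_site: float = 0.05
    sel_mix: tuple = (0.6, 0.395, 0.005)
    sel_coeffs: tuple = (0.0, -9.0, 100.0)
    pathogenic_enrichment_bd: float = 3.0
    pathogenic_base_rate: float = 0.15
    n_pwms: int = 3
    motif_len: int = 8
    crm_len: int = 800

    def __post_init__(self):
        if self.n_tf_genes > self.n_genes:
            raise ValueError("n_tf_genes must not exceed n_genes")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if not 0 <= self.bd_fraction <= 1:
            raise ValueError("bd_fraction must lie in [0, 1]")
        if abs(sum(self.sel_mix) - 1.0) > 1e-9 or any(f < 0 for f in self.sel_mix):
            raise ValueError("sel_mix fractions must be non-negative and sum to 1")
        if self.pathogenic_enrichment_bd < 0:
            raise ValueError("pathogenic_enrichment_bd must be non-negative")
        min_flank = self.crm_len + 2
        if self.n_crms > 0 and self.flank_len < min_flank:
            raise ValueError(
                f"impossible packing: flank_len {self.flank_len} cannot host a {self.crm_len} bp CRM"
            )
        if self.crm_len < self.motifs_per_crm * (self.motif_len + 4):
            raise ValueError("impossible packing: CRM too short for the requested motif instances")

    def expected_alpha(self) -> float:
        """Adaptive share of expected nonsynonymous divergence under this mix."""
        weights = [f * relative_fixation(g) for f, g in zip(self.sel_mix, self.sel_coeffs)]
        total = sum(weights)
        adaptive = sum(w for w, g in zip(weights, self.sel_coeffs) if g > 0)
        return adaptive / total if total > 0 else 0.0


def relative_fixation(gamma: float) -> float:
    """Fixation probability of a 2Ns = gamma mutation relative to neutral."""
    if gamma == 0.0:
        return 1.0
    return gamma / (1.0 - np.exp(-gamma))


def sfs_class_expectations(gamma: float, n: int, n_quad: int = 2000) -> np.ndarray:
    """Expected segregating sites per class k = 1..n-1, per unit theta*L.

    Numerical quadrature of H(gamma, q) against the binomial sampling kernel.
    """
    q = np.linspace(1e-6, 1.0 - 1e-6, n_quad)
    if gamma == 0.0:
        h = 1.0 / q
    else:
        h = (1.0 - np.exp(-gamma * (1.0 - q))) / ((1.0 - np.exp(-gamma)) * q * (1.0 - q))
    from scipy.stats import binom

    k = np.arange(1, n)
    kernel = binom.pmf(k[:, None], n, q[None, :])
    return np.trapezoid(kernel * h[None, :], q, axis=1)


@dataclass
class GenomeFixture:
    config: FixtureConfig
    reference: dict  # contig -> sequence string
    gene_models: list  # TranscriptModel
    region_catalog: RegionCatalog
    pwms: list
    crm_intervals: list  # all CRMs (pre-filter), with scores
    tfbs_all: list  # every planted motif interval (catalog holds only retained ones)
    truth: pd.DataFrame | None = None

    @property
    def coding_positions(self) -> np.ndarray:
        pos = []
        for t in self.gene_models:
            pos.append(np.arange(t.start, t.end))
        return np.concatenate(pos)


@dataclass
class PopulationSample:
    variants: pd.DataFrame  # one row per segregating site
    carriers: list  # per-variant array of carrier haplotype indices
    outgroup: dict  # contig -> aligned sequence
    sample_size: int
    divergence_truth: dict  # realized substitution counts by class


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons)
    return "".join(codons)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _make_pwms(rng: np.random.Generator, config: FixtureConfig) -> list:
    pwms = []
    for i in range(config.n_pwms):
        raw = np.full((4, config.motif_len), 40.0)
        dominant = rng.integers(0, 4, size=config.motif_len)
        raw[dominant, np.arange(config.motif_len)] = 880.0
        pwms.append(pwm_from_counts(raw, pseudocount=1.0, name=f"MA{i:04d}.1"))
    return pwms


def generate_fixture(config: FixtureConfig) -> GenomeFixture:
    """Deterministically build the genome, annotations, CRMs, and planted motifs."""
    rng = np.random.default_rng(config.seed)
    cds_len = 3 * config.codons_per_gene

    seq_parts: list[str] = []
    gene_models: list[TranscriptModel] = []
    flanks: list[tuple[int, int]] = []
    offset = 0
    for g in range(config.n_genes):
        flanks.append((offset, offset + config.flank_len))
        seq_parts.append(_random_seq(rng, config.flank_len))
        offset += config.flank_len
        gene_models.append(
            TranscriptModel(f"gene{g:04d}", CONTIG, offset, offset + cds_len, "+", g < config.n_tf_genes)
        )
        seq_parts.append(_random_cds(rng, config.codons_per_gene))
        offset += cds_len
    flanks.append((offset, offset + config.flank_len))
    seq_parts.append(_random_seq(rng, config.flank_len))
    offset += config.flank_len
    sequence = list("".join(seq_parts))

    pwms = _make_pwms(rng, config)

    crms: list[GenomicInterval] = []
    tfbs_all: list[GenomicInterval] = []
    lo, hi = config.crm_score_range
    for c in range(config.n_crms):
        fs, fe = flanks[c % len(flanks)]
        start = int(rng.integers(fs, fe - config.crm_len + 1))
        score = int(rng.integers(lo, hi + 1))
        crm = GenomicInterval(CONTIG, start, start + config.crm_len, "+", CRM, score)
        crms.append(crm)
        stride = config.crm_len // config.motifs_per_crm
        for m in range(config.motifs_per_crm):
            pwm = pwms[int(rng.integers(0, len(pwms)))]
            jitter = int(rng.integers(0, stride - config.motif_len + 1))
            mstart = start + m * stride + jitter
            sequence[mstart : mstart + config.motif_len] = pwm.consensus
            tfbs_all.append(GenomicInterval(CONTIG, mstart, mstart + config.motif_len, "+", TFBS))

    reference = {CONTIG: "".join(sequence)}

    catalog = RegionCatalog()
    for t in gene_models:
        catalog.transcripts[t.gene_id] = t
        catalog.add(ALLGENES, GenomicInterval(CONTIG, t.start, t.end, "+", ALLGENES))
        if t.is_tf:
            bd_codons = int(round(config.bd_fraction * config.codons_per_gene))
            if bd_codons > 0:
                start_codon = (config.codons_per_gene - bd_codons) // 2
                bd_iv = GenomicInterval(
                    CONTIG, t.start + 3 * start_codon, t.start + 3 * (start_codon + bd_codons), "+", BD
                )
                catalog.add(BD, bd_iv)
                for s, e in complement_domains((t.start, t.end), [bd_iv]):
                    catalog.add(NONBD, GenomicInterval(CONTIG, s, e, "+", NONBD))
            else:
                for s, e in [(t.start, t.end)]:
                    catalog.add(NONBD, GenomicInterval(CONTIG, s, e, "+", NONBD))
    retained = filter_crms(crms, gene_models)
    retained_keys = {(c.start, c.end) for c in retained}
    for crm in retained:
        catalog.add(CRM, crm)
    for site in tfbs_all:
        if any(site.start >= s and site.end <= e for s, e in retained_keys):
            catalog.add(TFBS, site)

    return GenomeFixture(config, reference, gene_models, catalog, pwms, crms, tfbs_all)


def _coding_site_weights(fixture: GenomeFixture):
    """Per coding position: syn-alt and nonsyn-alt lists."""
    ref = fixture.reference[CONTIG]
    positions, syn_alts, nonsyn_alts = [], [], []
    for t in fixture.gene_models:
        lookup = codonsites.nonsyn_lookup(ref[t.start : t.end])
        for p, entry in enumerate(lookup):
            positions.append(t.start + p)
            syn_alts.append([b for b, ns in entry.items() if not ns])
            nonsyn_alts.append([b for b, ns in entry.items() if ns])
    return np.asarray(positions), syn_alts, nonsyn_alts


def generate_population(fixture: GenomeFixture, config: FixtureConfig | None = None) -> PopulationSample:
    """Draw segregating variants, the outgroup contig, and truth labels."""
    config = config or fixture.config
    if config.sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    rng = np.random.default_rng(config.seed + 1)
    n = config.sample_size
    ref = fixture.reference[CONTIG]
    L_total = len(ref)

    positions, syn_alts, nonsyn_alts = _coding_site_weights(fixture)
    syn_w = np.array([len(a) / 3.0 for a in syn_alts])
    nonsyn_w = np.array([len(a) / 3.0 for a in nonsyn_alts])
    L_syn, L_nonsyn = syn_w.sum(), nonsyn_w.sum()

    catalog = fixture.region_catalog
    tfbs_pos = sorted(
        {p for iv in catalog.intervals[TFBS] for p in range(iv.start, iv.end)}
    )
    coding_set = set(positions.tolist())
    tfbs_pos = np.asarray([p for p in tfbs_pos if p not in coding_set], dtype=int)
    noncoding_other = np.asarray(
        sorted(set(range(L_total)) - coding_set - set(tfbs_pos.tolist())), dtype=int
    )

    e_cache = {g: sfs_class_expectations(g, n) for g in set(config.sel_coeffs) | {0.0}}
    theta = config.theta_per_site

    used: set[int] = set()
    rows, carriers = [], []

    def draw_carriers(k: int) -> np.ndarray:
        return np.sort(rng.choice(n, size=k, replace=False))

    def place(length: float, gamma: float, sampler, var_class: str, sel_class: str):
        e_k = e_cache[gamma]
        counts = rng.poisson(theta * length * e_k)
        for k_idx, c in enumerate(counts):
            k = k_idx + 1
            for _ in range(c):
                for _attempt in range(200):
                    pos, alt = sampler()
                    if pos not in used:
                        break
                else:
                    continue
                used.add(pos)
                rows.append(
                    {
                        "contig": CONTIG,
                        "pos": int(pos),
                        "ref": ref[pos],
                        "alt": alt,
                        "k": k,
                        "n": n,
                        "var_class": var_class,
                        "sel_class": sel_class,
                        "gamma": gamma,
                    }
                )
                carriers.append(draw_carriers(k))

    def coding_sampler(weights, alts):
        cum = np.cumsum(weights)
        total = cum[-1]

        def sample():
            r = rng.random() * total
            i = int(np.searchsorted(cum, r))
            pos = int(positions[i])
            alt = alts[i][int(rng.integers(0, len(alts[i])))]
            return pos, alt

        return sample

    def uniform_sampler(pool):
        def sample():
            pos = int(pool[int(rng.integers(0, len(pool)))])
            alt = BASES[int(rng.integers(0, 4))]
            while alt == ref[pos]:
                alt = BASES[int(rng.integers(0, 4))]
            return pos, alt

        return sample

    # synonymous: always neutral
    place(L_syn, 0.0, coding_sampler(syn_w, syn_alts), codonsites.SYNONYMOUS, "neutral")
    # nonsynonymous: mixture
    for frac, gamma, name in zip(config.sel_mix, config.sel_coeffs, ("neutral", "deleterious", "beneficial")):
        if frac > 0:
            place(
                frac * L_nonsyn, gamma, coding_sampler(nonsyn_w, nonsyn_alts), codonsites.NONSYNONYMOUS, name
            )
    # TFBS noncoding: same selective mixture (the "nonsynonymous equivalent")
    if len(tfbs_pos):
        for frac, gamma, name in zip(config.sel_mix, config.sel_coeffs, ("neutral", "deleterious", "beneficial")):
            if frac > 0:
                place(frac * len(tfbs_pos), gamma, uniform_sampler(tfbs_pos), "tfbs", name)
    # remaining noncoding: neutral background
    if len(noncoding_other):
        place(len(noncoding_other), 0.0, uniform_sampler(noncoding_other), "noncoding", "neutral")

    variants = pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "k", "n", "var_class", "sel_class", "gamma"],
    )
    order = np.argsort(variants["pos"].to_numpy(), kind="stable") if len(variants) else []
    variants = variants.iloc[order].reset_index(drop=True)
    carriers = [carriers[i] for i in order]

    # outgroup: Bernoulli substitutions, thinned by constraint
    f_neu, f_del, f_ben = config.sel_mix
    g_neu, g_del, g_ben = config.sel_coeffs
    c_mix = (
        f_neu * relative_fixation(g_neu)
        + f_del * relative_fixation(g_del)
        + f_ben * relative_fixation(g_ben)
    )
    adaptive_share = (f_ben * relative_fixation(g_ben) / c_mix) if c_mix > 0 else 0.0
    d = config.divergence_per_site
    out_seq = list(ref)
    div_truth = {"syn": 0, "nonsyn": 0, "nonsyn_adaptive": 0, "tfbs": 0, "noncoding": 0}

    for i, pos in enumerate(positions):
        p_syn = d * syn_w[i]
        p_non = d * nonsyn_w[i] * c_mix
        r = rng.random()
        if r < p_syn:
            alts = syn_alts[i]
            out_seq[pos] = alts[int(rng.integers(0, len(alts)))]
            div_truth["syn"] += 1
        elif r < p_syn + p_non and nonsyn_alts[i]:
            alts = nonsyn_alts[i]
            out_seq[pos] = alts[int(rng.integers(0, len(alts)))]
            div_truth["nonsyn"] += 1
            if rng.random() < adaptive_share:
                div_truth["nonsyn_adaptive"] += 1
    for pos in tfbs_pos:
        if rng.random() < d * c_mix:
            out_seq[pos] = _other_base(rng, ref[pos])
            div_truth["tfbs"] += 1
    for pos in noncoding_other:
        if rng.random() < d:
            out_seq[pos] = _other_base(rng, ref[pos])
            div_truth["noncoding"] += 1

    # pathogenicity labels for nonsynonymous variants inside TF genes
    labels = []
    base_odds = config.pathogenic_base_rate / (1 - config.pathogenic_base_rate)
    for _, row in variants.iterrows():
        label = ""
        if row.var_class == codonsites.NONSYNONYMOUS:
            region_labels = catalog.labels_at(CONTIG, row.pos)
            if BD in region_labels or NONBD in region_labels:
                odds = base_odds * (config.pathogenic_enrichment_bd if BD in region_labels else 1.0)
                p = odds / (1 + odds)
                label = "pathogenic" if rng.random() < p else "benign"
        labels.append(label)
    variants["clinical"] = labels

    fixture.truth = variants.copy()
    return PopulationSample(variants, carriers, {CONTIG: "".join(out_seq)}, n, div_truth)


def _other_base(rng: np.random.Generator, base: str) -> str:
    alt = BASES[int(rng.integers(0, 4))]
    while alt == base:
        alt = BASES[int(rng.integers(0, 4))]
    return alt


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_fixture(fixture: GenomeFixture, population: PopulationSample, outdir) -> dict:
    """Write FASTA / GFF3 / BED / VCF / JASPAR / TSV files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "outgroup": outdir / "outgroup.fa",
        "genes": outdir / "genes.gff3",
        "bd": outdir / "bd.bed",
        "nonbd": outdir / "nonbd.bed",
        "crm": outdir / "crm.bed",
        "tfbs": outdir / "tfbs.bed",
        "vcf": outdir / "variants.vcf",
        "pwms": outdir / "pwms.jaspar",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }

    _write_fasta(paths["reference"], fixture.reference)
    _write_fasta(paths["outgroup"], population.outgroup)
    _write_gff3(paths["genes"], fixture)
    catalog = fixture.region_catalog
    _write_bed(paths["bd"], catalog.intervals[BD])
    _write_bed(paths["nonbd"], catalog.intervals[NONBD])
    _write_bed(paths["crm"], fixture.crm_intervals)
    _write_bed(paths["tfbs"], catalog.intervals[TFBS])
    _write_vcf(paths["vcf"], fixture, population)
    _write_jaspar(paths["pwms"], fixture.pwms)
    population.variants.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(fixture.config)
    paths["config"].write_text(json.dumps(cfg, indent=2, default=list) + "\n")
    return paths


def _write_fasta(path: Path, sequences: dict, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_gff3(path: Path, fixture: GenomeFixture) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in fixture.gene_models:
            base = f"{t.contig}\ttfselect\t"
            attrs_gene = f"ID={t.gene_id};is_tf={'1' if t.is_tf else '0'}"
            fh.write(base + f"gene\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs_gene}\n")
            fh.write(
                base
                + f"mRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\tID={t.gene_id}.t1;Parent={t.gene_id}\n"
            )
            fh.write(
                base
                + f"CDS\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t0\tID={t.gene_id}.cds;Parent={t.gene_id}.t1\n"
            )


def _write_bed(path: Path, intervals) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(sorted(intervals, key=lambda v: (v.contig, v.start, v.end))):
            score = iv.score if iv.score is not None else 0
            label = iv.label or "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{label}_{i}\t{score}\t{iv.strand}\n")


def _write_vcf(path: Path, fixture: GenomeFixture, population: PopulationSample) -> None:
    n = population.sample_size
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tfselect-synthetic\n")
        for contig, seq in sorted(fixture.reference.items()):
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [f"hap{i:03d}" for i in range(n)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (row, carr) in zip(population.variants.itertuples(), population.carriers):
            gts = np.zeros(n, dtype=int)
            gts[carr] = 1
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(str(g) for g in gts)
                + "\n"
            )


def _write_jaspar(path: Path, pwms) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\t{pwm.name}\n")
            for b, row in zip(BASES, pwm.counts):
                fh.write(f"{b}  [ " + " ".join(f"{int(v):5d}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# readers (round-trip support for the analysis pipeline)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            label = f[3].rsplit("_", 1)[0] if len(f) > 3 and f[3] != "." else None
            out.append(
                GenomicInterval(
                    f[0],
                    int(f[1]),
                    int(f[2]),
                    f[5] if len(f) > 5 else ".",
                    label if label in ("BD", "NONBD", "ALLGENES", "CRM", "TFBS") else None,
                    int(f[4]) if len(f) > 4 else None,
                )
            )
    return out


def read_gff3_transcripts(path) -> list:
    transcripts = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            transcripts.append(
                TranscriptModel(
                    attrs.get("ID", f"{f[0]}:{f[3]}"),
                    f[0],
                    int(f[3]) - 1,
                    int(f[4]),
                    f[6],
                    attrs.get("is_tf", "0") == "1",
                )
            )
    return transcripts


def read_vcf(path):
    """Read a haploid-genotype VCF into (variants DataFrame, carriers list)."""
    import pysam

    rows, carriers = [], []
    with pysam.VariantFile(str(path)) as vcf:
        n = len(vcf.header.samples)
        for rec in vcf:
            gts = np.array(
                [rec.samples[s]["GT"][0] or 0 for s in vcf.header.samples], dtype=int
            )
            rows.append(
                {
                    "contig": rec.chrom,
                    "pos": rec.pos - 1,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "k": int(gts.sum()),
                    "n": n,
                }
            )
            carriers.append(np.flatnonzero(gts))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "k", "n"]), carriers


def read_jaspar(path) -> list:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        raw = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        out.append(pwm_from_counts(raw, pseudocount=0.0, name=m.matrix_id or m.name))
    return out
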