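"""End-to-end analysis: polarization, classification, region labeling,
constraint ratios, MK alpha with frequency cutoffs, and enrichment tests.

The same analysis runs on an in-memory fixture or on a fixture directory written
by ``synthetic_data.write_fixture``. Constraint ratios use the count-proportion
estimator (nonsynonymous and synonymous variant counts normalized by their
Nei-Gojobori site lengths); ``pi_mode="pairwise"`` weights each variant by its
heterozygosity 2k(n-k)/(n(n-1)) instead, giving classical average pairwise
diversity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import codonsites, selstats
from .regions import ALLGENES, BD, CRM, NONBD, TFBS, RegionCatalog, assign_variants
from .synthetic_data import (
    GenomeFixture,
    PopulationSample,
    read_bed,
    read_fasta,
    read_gff3_transcripts,
    read_vcf,
)

CODING_CLASSES = (BD, NONBD, ALLGENES)


@dataclass
class AnalysisInputs:
    reference: dict
    outgroup: dict
    transcripts: dict  # gene_id -> TranscriptModel
    catalog: RegionCatalog
    variants: pd.DataFrame  # contig,pos,ref,alt,k,n (+clinical optional)
    crms: list = field(default_factory=list)


@dataclass
class AnalysisResult:
    constraint: pd.DataFrame
    alpha_table: pd.DataFrame
    curve_table: pd.DataFrame
    enrichment: dict
    welch: pd.DataFrame
    cutoffs: selstats.FrequencyCutoffs
    counts_log: dict
    estimates: dict  # region class -> ConstraintEstimate (polymorphism mode)


def inputs_from_fixture(fixture: GenomeFixture, population: PopulationSample) -> AnalysisInputs:
    cols = ["contig", "pos", "ref", "alt", "k", "n"]
    if "clinical" in population.variants:
        cols = cols + ["clinical"]
    return AnalysisInputs(
        reference=fixture.reference,
        outgroup=population.outgroup,
        transcripts=fixture.region_catalog.transcripts,
        catalog=fixture.region_catalog,
        variants=population.variants[cols].copy(),
        crms=list(fixture.region_catalog.intervals[CRM]),
    )


def inputs_from_dir(path) -> AnalysisInputs:
    path = Path(path)
    reference = read_fasta(path / "reference.fa")
    outgroup = read_fasta(path / "outgroup.fa")
    transcripts = {t.gene_id: t for t in read_gff3_transcripts(path / "genes.gff3")}
    catalog = RegionCatalog()
    catalog.transcripts = transcripts
    for t in transcripts.values():
        from .regions import GenomicInterval

        catalog.add(ALLGENES, GenomicInterval(t.contig, t.start, t.end, t.strand, ALLGENES))
    for name, label in (("bd.bed", BD), ("nonbd.bed", NONBD), ("tfbs.bed", TFBS)):
        for iv in read_bed(path / name):
            catalog.add(label, iv)
    crms = read_bed(path / "crm.bed")
    from .regions import filter_crms

    for crm in filter_crms(crms, transcripts.values()):
        catalog.add(CRM, crm)
    variants, _ = read_vcf(path / "variants.vcf")
    truth_path = path / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        if "clinical" in truth and len(truth) == len(variants):
            variants["clinical"] = truth["clinical"].fillna("").astype(str).values
    return AnalysisInputs(reference, outgroup, transcripts, catalog, variants, crms)


# ---------------------------------------------------------------------------
# classification and polarization
# ---------------------------------------------------------------------------

def _transcript_tree(inputs: AnalysisInputs) -> dict:
    trees: dict[str, IntervalTree] = {}
    for t in inputs.transcripts.values():
        trees.setdefault(t.contig, IntervalTree()).addi(t.start, t.end, t)
    return trees


def annotate_variants(inputs: AnalysisInputs) -> tuple[pd.DataFrame, dict]:
    """Polarize against the outgroup, classify coding variants, label regions.

    Returns (annotated variants, counts log). Rejected sites (outgroup matches
    neither allele) are excluded from frequency-based statistics but tallied.
    """
    trees = _transcript_tree(inputs)
    lookup_cache: dict[str, list] = {}
    rows = []
    n_rejected = 0
    for v in inputs.variants.itertuples():
        og = inputs.outgroup[v.contig][v.pos]
        pol = codonsites.polarize(v.pos, v.ref, v.alt, v.n - v.k, v.k, og)
        if pol is None:
            n_rejected += 1
            continue
        var_class = "noncoding"
        hits = trees.get(v.contig, IntervalTree()).at(v.pos)
        if hits:
            t = next(iter(hits)).data
            if t.gene_id not in lookup_cache:
                lookup_cache[t.gene_id] = codonsites.nonsyn_lookup(
                    inputs.reference[t.contig][t.start : t.end]
                )
            entry = lookup_cache[t.gene_id][v.pos - t.start]
            var_class = (
                codonsites.NONSYNONYMOUS if entry[v.alt] else codonsites.SYNONYMOUS
            )
        labels = inputs.catalog.labels_at(v.contig, v.pos)
        if TFBS in labels and var_class == "noncoding":
            var_class = "tfbs"
        rows.append(
            {
                "contig": v.contig,
                "pos": v.pos,
                "ancestral": pol.ancestral,
                "derived": pol.derived,
                "k": pol.k,
                "n": pol.n,
                "freq": pol.frequency,
                "var_class": var_class,
                "labels": ",".join(sorted(labels)),
                "clinical": getattr(v, "clinical", "") or "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ancestral", "derived", "k", "n", "freq",
            "var_class", "labels", "clinical",
        ],
    )
    log = {"input": len(inputs.variants), "rejected_polarization": n_rejected, "analyzed": len(df)}
    return df, log


def _class_intervals_per_gene(inputs: AnalysisInputs, label: str) -> dict:
    """gene_id -> list of (start, end) of a coding class within that gene."""
    out: dict[str, list] = {}
    for t in inputs.transcripts.values():
        ivs = []
        for iv in inputs.catalog.intervals[label]:
            if iv.contig == t.contig and iv.start >= t.start and iv.end <= t.end:
                ivs.append((iv.start, iv.end))
        if ivs:
            out[t.gene_id] = sorted(ivs)
    return out


def divergence_sites(inputs: AnalysisInputs, polymorphic: set) -> pd.DataFrame:
    """Fixed differences vs the outgroup, with syn/nonsyn class for coding sites.

    Positions currently polymorphic in the population are excluded.
    """
    rows = []
    trees = _transcript_tree(inputs)
    for contig, ref in inputs.reference.items():
        out = inputs.outgroup[contig]
        ref_a = np.frombuffer(ref.encode(), dtype=np.uint8)
        out_a = np.frombuffer(out.encode(), dtype=np.uint8)
        diff_pos = np.flatnonzero(ref_a != out_a)
        lookup_cache: dict[str, list] = {}
        for pos in diff_pos:
            pos = int(pos)
            if (contig, pos) in polymorphic:
                continue
            var_class = "noncoding"
            hits = trees.get(contig, IntervalTree()).at(pos)
            if hits:
                t = next(iter(hits)).data
                if t.gene_id not in lookup_cache:
                    lookup_cache[t.gene_id] = codonsites.nonsyn_lookup(ref[t.start : t.end])
                entry = lookup_cache[t.gene_id][pos - t.start]
                alt = out[pos]
                var_class = (
                    codonsites.NONSYNONYMOUS if entry.get(alt, True) else codonsites.SYNONYMOUS
                )
            labels = inputs.catalog.labels_at(contig, pos)
            if TFBS in labels and var_class == "noncoding":
                var_class = "tfbs"
            rows.append(
                {"contig": contig, "pos": pos, "var_class": var_class, "labels": ",".join(sorted(labels))}
            )
    return pd.DataFrame(rows, columns=["contig", "pos", "var_class", "labels"])


# ---------------------------------------------------------------------------
# constraint ratios
# ---------------------------------------------------------------------------

def _variant_weight(df: pd.DataFrame, pi_mode: str) -> np.ndarray:
    if pi_mode == "counts":
        return np.ones(len(df))
    if pi_mode == "pairwise":
        k, n = df["k"].to_numpy(float), df["n"].to_numpy(float)
        return 2 * k * (n - k) / (n * (n - 1))
    raise ValueError(f"unknown pi_mode {pi_mode!r}")


def coding_constraint_units(
    inputs: AnalysisInputs,
    variants: pd.DataFrame,
    label: str,
    pi_mode: str = "counts",
) -> list:
    """Per-gene (test_count, test_sites, neutral_count, neutral_sites) tuples."""
    per_gene = _class_intervals_per_gene(inputs, label)
    v = variants[variants["labels"].str.contains(label, na=False)]
    w = _variant_weight(v, pi_mode)
    units = []
    for gene_id, ivs in per_gene.items():
        t = inputs.transcripts[gene_id]
        seq = inputs.reference[t.contig]
        sites = codonsites.SiteCounts(0.0, 0.0)
        for s, e in ivs:
            sites = sites + codonsites.ng_site_counts(seq[s:e])
        in_gene = (v["contig"] == t.contig) & v["pos"].between(t.start, t.end - 1)
        sel = v[in_gene]
        wsel = w[in_gene.to_numpy()]
        nonsyn = wsel[(sel["var_class"] == codonsites.NONSYNONYMOUS).to_numpy()].sum()
        syn = wsel[(sel["var_class"] == codonsites.SYNONYMOUS).to_numpy()].sum()
        units.append((nonsyn, sites.L_nonsyn, syn, sites.L_syn))
    return units


def tfbs_constraint_units(
    inputs: AnalysisInputs,
    variants: pd.DataFrame,
    neutral_count: float,
    neutral_sites: float,
    pi_mode: str = "counts",
) -> list:
    """Per-CRM units; the neutral (All-genes synonymous) totals are shared.

    Bootstrap resampling therefore varies the binding-site numerator only.
    """
    tf = variants[variants["var_class"] == "tfbs"]
    w = _variant_weight(tf, pi_mode)
    crms = inputs.catalog.intervals[CRM]
    n_crms = max(len(crms), 1)
    units = []
    for crm in crms:
        tfbs_len = 0
        for iv in inputs.catalog.intervals[TFBS]:
            if iv.contig == crm.contig and iv.start >= crm.start and iv.end <= crm.end:
                tfbs_len += len(iv)
        inside = ((tf["contig"] == crm.contig) & tf["pos"].between(crm.start, crm.end - 1)).to_numpy()
        count = w[inside].sum()
        units.append((count, max(tfbs_len, 1e-9), neutral_count / n_crms, neutral_sites / n_crms))
    return units


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def analyze(
    inputs: AnalysisInputs,
    n_reps: int = selstats.DEFAULT_N_REPS,
    n_classes: int = selstats.DEFAULT_N_CLASSES,
    delta: float = 0.1,
    f_high: float = selstats.DEFAULT_F_HIGH,
    f_low_override: float | None = None,
    pi_mode: str = "counts",
    seed: int = 0,
) -> AnalysisResult:
    variants, log = annotate_variants(inputs)
    polymorphic = set(zip(variants["contig"], variants["pos"]))
    divergence = divergence_sites(inputs, polymorphic)

    # --- constraint ratios (polymorphism and divergence modes)
    constraint_rows = []
    estimates: dict[str, selstats.ConstraintEstimate] = {}
    ag_syn = variants[
        variants["labels"].str.contains(ALLGENES, na=False)
        & (variants["var_class"] == codonsites.SYNONYMOUS)
    ]
    ag_units = coding_constraint_units(inputs, variants, ALLGENES, pi_mode)
    ag_syn_sites = sum(u[3] for u in ag_units)
    ag_syn_count = float(_variant_weight(ag_syn, pi_mode).sum())

    div_by_class: dict[str, tuple] = {}
    for label in CODING_CLASSES:
        per_gene = _class_intervals_per_gene(inputs, label)
        dn = ds = 0
        sites = codonsites.SiteCounts(0.0, 0.0)
        for gene_id, ivs in per_gene.items():
            t = inputs.transcripts[gene_id]
            seq = inputs.reference[t.contig]
            for s, e in ivs:
                sites = sites + codonsites.ng_site_counts(seq[s:e])
                sel = divergence[
                    (divergence["contig"] == t.contig) & divergence["pos"].between(s, e - 1)
                ]
                dn += int((sel["var_class"] == codonsites.NONSYNONYMOUS).sum())
                ds += int((sel["var_class"] == codonsites.SYNONYMOUS).sum())
        div_by_class[label] = (dn, ds, sites.L_nonsyn, sites.L_syn)

    for label in CODING_CLASSES:
        units = coding_constraint_units(inputs, variants, label, pi_mode)
        if units:
            try:
                est = selstats.constraint_ratio_bootstrap(
                    units, label, "polymorphism", n_reps=n_reps, seed=seed
                )
                estimates[label] = est
                constraint_rows.append(_constraint_row(est))
            except ValueError:
                constraint_rows.append(_na_row(label, "polymorphism"))
        dn, ds, ln, ls = div_by_class[label]
        if ds > 0:
            kn_ks = selstats.constraint_ratio(dn, ln, ds, ls)
            constraint_rows.append(
                {
                    "region_class": label, "mode": "divergence", "estimate": kn_ks,
                    "test_count": dn, "test_sites": ln, "neutral_count": ds,
                    "neutral_sites": ls, "ci_low": np.nan, "ci_high": np.nan,
                }
            )
        else:
            constraint_rows.append(_na_row(label, "divergence"))

    tfbs_len_total = inputs.catalog.class_length(TFBS)
    if tfbs_len_total > 0 and ag_syn_count > 0:
        units = tfbs_constraint_units(inputs, variants, ag_syn_count, ag_syn_sites, pi_mode)
        try:
            est = selstats.constraint_ratio_bootstrap(
                units, TFBS, "polymorphism", n_reps=n_reps, seed=seed
            )
            estimates[TFBS] = est
            constraint_rows.append(_constraint_row(est))
        except ValueError:
            constraint_rows.append(_na_row(TFBS, "polymorphism"))
        d_tfbs = int((divergence["var_class"] == "tfbs").sum())
        _, ag_ds, _, ag_ls = div_by_class[ALLGENES]
        if ag_ds > 0:
            constraint_rows.append(
                {
                    "region_class": TFBS, "mode": "divergence",
                    "estimate": selstats.constraint_ratio(d_tfbs, tfbs_len_total, ag_ds, ag_ls),
                    "test_count": d_tfbs, "test_sites": tfbs_len_total,
                    "neutral_count": ag_ds, "neutral_sites": ag_ls,
                    "ci_low": np.nan, "ci_high": np.nan,
                }
            )
    else:
        constraint_rows.append(_na_row(TFBS, "polymorphism"))

    constraint = pd.DataFrame(constraint_rows)

    # --- SFS, asymptotic fit on All genes, cutoffs, pooled MK per class
    curve_rows, alpha_rows = [], []
    cutoffs = selstats.FrequencyCutoffs(0.0, f_high)
    ag = variants[variants["labels"].str.contains(ALLGENES, na=False)]
    fn = ag.loc[ag["var_class"] == codonsites.NONSYNONYMOUS, "freq"].to_numpy()
    fs = ag.loc[ag["var_class"] == codonsites.SYNONYMOUS, "freq"].to_numpy()
    ag_dn, ag_ds, _, _ = div_by_class[ALLGENES]
    fit = None
    if ag_dn > 0 and ag_ds > 0 and len(fs):
        pn = selstats.build_sfs(fn, n_classes)
        ps = selstats.build_sfs(fs, n_classes)
        curve = selstats.alpha_curve(pn, ps, ag_dn, ag_ds)
        try:
            fit = selstats.fit_asymptote(curve, fit_range=(0.0, f_high), n_reps=0, seed=seed)
            cutoffs = selstats.select_cutoffs(fit, curve, delta=delta, f_high=f_high)
        except ValueError:
            fit = None
        for m, a, qn, qs in zip(curve.midpoints, curve.alpha, curve.pn, curve.ps):
            curve_rows.append(
                {"region_class": ALLGENES, "midpoint": m, "alpha": a, "pn": qn, "ps": qs}
            )
    if f_low_override is not None:
        cutoffs = selstats.FrequencyCutoffs(f_low_override, f_high)

    for label in (*CODING_CLASSES, TFBS):
        if label == TFBS:
            sel = variants[variants["var_class"] == "tfbs"]
            fn_c = sel["freq"].to_numpy()
            fs_c = ag.loc[ag["var_class"] == codonsites.SYNONYMOUS, "freq"].to_numpy()
            dn = int((divergence["var_class"] == "tfbs").sum())
            ds = div_by_class[ALLGENES][1]
        else:
            sel = variants[variants["labels"].str.contains(label, na=False)]
            fn_c = sel.loc[sel["var_class"] == codonsites.NONSYNONYMOUS, "freq"].to_numpy()
            fs_c = sel.loc[sel["var_class"] == codonsites.SYNONYMOUS, "freq"].to_numpy()
            dn, ds = div_by_class[label][0], div_by_class[label][1]
        try:
            res = selstats.pooled_mk_alpha(
                fn_c, fs_c, dn, ds, cutoffs, n_reps=n_reps, seed=seed,
                resample_divergence=True,
            )
            alpha_rows.append(
                {
                    "region_class": label, "alpha": res.alpha,
                    "ci_low": res.ci[0] if res.ci else np.nan,
                    "ci_high": res.ci[1] if res.ci else np.nan,
                    "Pn": res.Pn, "Ps": res.Ps, "Dn": res.Dn, "Ds": res.Ds,
                }
            )
        except ValueError:
            alpha_rows.append(
                {
                    "region_class": label, "alpha": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "Pn": 0, "Ps": 0, "Dn": dn, "Ds": ds,
                }
            )

    # --- pathogenic enrichment BD vs non-BD
    enrichment = {}
    if "clinical" in variants and (variants["clinical"] != "").any():
        lab = variants[variants["clinical"].isin(["pathogenic", "benign"])]
        in_bd = lab["labels"].str.split(",").apply(lambda ls: BD in ls)
        in_nonbd = lab["labels"].str.split(",").apply(lambda ls: NONBD in ls)
        pb = int(((lab["clinical"] == "pathogenic") & in_bd).sum())
        bb = int(((lab["clinical"] == "benign") & in_bd).sum())
        pn_ = int(((lab["clinical"] == "pathogenic") & in_nonbd).sum())
        bn_ = int(((lab["clinical"] == "benign") & in_nonbd).sum())
        odds, p, prop_bd, prop_nonbd = selstats.pathogenic_enrichment(pb, bb, pn_, bn_)
        enrichment = {
            "pathogenic_bd": pb, "benign_bd": bb, "pathogenic_nonbd": pn_,
            "benign_nonbd": bn_, "odds_ratio": odds, "p_value": p,
            "proportion_bd": prop_bd, "proportion_nonbd": prop_nonbd,
        }

    # --- Welch comparisons between bootstrap replicate distributions
    welch_rows = []
    for a, b in ((BD, NONBD), (BD, ALLGENES), (NONBD, ALLGENES), (TFBS, ALLGENES)):
        if a in estimates and b in estimates:
            t, p = selstats.compare_classes_welch(estimates[a].replicates, estimates[b].replicates)
            welch_rows.append({"class_a": a, "class_b": b, "t": t, "p_value": p})
    welch = pd.DataFrame(welch_rows, columns=["class_a", "class_b", "t", "p_value"])

    log["divergence_sites"] = len(divergence)
    return AnalysisResult(
        constraint=constraint,
        alpha_table=pd.DataFrame(alpha_rows),
        curve_table=pd.DataFrame(curve_rows, columns=["region_class", "midpoint", "alpha", "pn", "ps"]),
        enrichment=enrichment,
        welch=welch,
        cutoffs=cutoffs,
        counts_log=log,
        estimates=estimates,
    )


def _constraint_row(est: selstats.ConstraintEstimate) -> dict:
    return {
        "region_class": est.region_class, "mode": est.mode, "estimate": est.estimate,
        "test_count": est.test_count, "test_sites": est.test_sites,
        "neutral_count": est.neutral_count, "neutral_sites": est.neutral_sites,
        "ci_low": est.ci[0], "ci_high": est.ci[1],
    }


def _na_row(label: str, mode: str) -> dict:
    return {
        "region_class": label, "mode": mode, "estimate": np.nan,
        "test_count": 0, "test_sites": 0, "neutral_count": 0, "neutral_sites": 0,
        "ci_low": np.nan, "ci_high": np.nan,
    }


def write_report(result: AnalysisResult, outdir, metadata: dict | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "constraint": outdir / "constraint.tsv",
        "alpha": outdir / "alpha.tsv",
        "curve": outdir / "alpha_curve.tsv",
        "welch": outdir / "welch.tsv",
        "summary": outdir / "summary.json",
    }
    float_fmt = "%.6g"
    result.constraint.to_csv(paths["constraint"], sep="\t", index=False, float_format=float_fmt)
    result.alpha_table.to_csv(paths["alpha"], sep="\t", index=False, float_format=float_fmt)
    result.curve_table.to_csv(paths["curve"], sep="\t", index=False, float_format=float_fmt)
    result.welch.to_csv(paths["welch"], sep="\t", index=False, float_format=float_fmt)
    summary = {
        "cutoffs": {"f_low": result.cutoffs.f_low, "f_high": result.cutoffs.f_high},
        "counts": result.counts_log,
        "enrichment": result.enrichment,
        "caveats": [
            "Welch tests compare bootstrap replicate distributions and understate uncertainty",
        ],
    }
    if metadata:
        summary["metadata"] = metadata
    paths["summary"].write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return paths
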