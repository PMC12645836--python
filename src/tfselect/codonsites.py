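"""Codon-level variant classification, Nei-Gojobori site counting, and outgroup polarization.

Coding variants are classified against the reference transcript codon (multiple hits
in one codon are treated independently, the standard approximation). Expected
synonymous/nonsynonymous site lengths follow the Nei-Gojobori (1986) convention:
each codon position contributes (number of synonymous single-base changes)/3 to the
synonymous length, with mutations to stop codons counted as nonsynonymous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"


@dataclass
class SiteCounts:
    """Expected synonymous / nonsynonymous site lengths (fractional)."""

    L_syn: float
    L_nonsyn: float

    @property
    def total(self) -> float:
        return self.L_syn + self.L_nonsyn

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.L_syn + other.L_syn, self.L_nonsyn + other.L_nonsyn)


@dataclass
class PolarizedVariant:
    """A biallelic SNP with ancestral/derived alleles assigned from an outgroup."""

    position: int
    ancestral: str
    derived: str
    k: int  # derived copies in the sample
    n: int  # sampled haplotypes
    var_class: str | None = None  # synonymous / nonsynonymous / tfbs / None
    labels: set = field(default_factory=set)

    @property
    def frequency(self) -> float:
        return self.k / self.n


def _codon_to_aa(table_id: int = 1) -> dict:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=None)
def _aa_map(table_id: int) -> dict:
    return _codon_to_aa(table_id)


def translate_codon(codon: str, table_id: int = 1) -> str:
    """Amino acid (or '*') for a codon under the given NCBI genetic code table."""
    codon = codon.upper()
    try:
        return _aa_map(table_id)[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def classify_variant(codon: str, offset: int, alt: str, table_id: int = 1) -> str:
    """Classify a single-base change in a codon as synonymous or nonsynonymous.

    ``offset`` is the 0-based position within the codon. Changes creating or
    destroying a stop codon are nonsynonymous.
    """
    codon = codon.upper()
    alt = alt.upper()
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0, 1 or 2, got {offset}")
    if alt not in BASES:
        raise ValueError(f"alt must be one of ACGT, got {alt!r}")
    if codon[offset] == alt:
        raise ValueError("alt equals the reference base")
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    return SYNONYMOUS if translate_codon(codon, table_id) == translate_codon(mutated, table_id) else NONSYNONYMOUS


@lru_cache(maxsize=None)
def codon_site_counts(codon: str, table_id: int = 1) -> SiteCounts:
    """Nei-Gojobori expected site counts for one codon (sums to 3)."""
    codon = codon.upper()
    if translate_codon(codon, table_id) == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    l_syn = 0.0
    for offset in range(3):
        n_syn = sum(
            1
            for b in BASES
            if b != codon[offset]
            and classify_variant(codon, offset, b, table_id) == SYNONYMOUS
        )
        l_syn += n_syn / 3.0
    return SiteCounts(l_syn, 3.0 - l_syn)


def ng_site_counts(seq: str, table_id: int = 1) -> SiteCounts:
    """Nei-Gojobori site counts for a coding sequence (length multiple of 3).

    A trailing stop codon is permitted and excluded from the counts; an internal
    stop or a non-ACGT base raises ``ValueError``.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    total = SiteCounts(0.0, 0.0)
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if translate_codon(codon, table_id) == "*":
            if i == n_codons - 1:
                continue
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        total = total + codon_site_counts(codon, table_id)
    return total


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def polarize(
    position: int,
    ref: str,
    alt: str,
    ref_count: int,
    alt_count: int,
    outgroup_base: str,
) -> PolarizedVariant | None:
    """Assign ancestral/derived alleles at a biallelic site using the outgroup.

    The allele matching the outgroup base is ancestral. Returns ``None`` when the
    outgroup base matches neither allele or is a gap/ambiguity code (the caller
    should tally the rejection).
    """
    ref, alt = ref.upper(), alt.upper()
    outgroup_base = outgroup_base.upper()
    n = ref_count + alt_count
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    if outgroup_base == ref:
        return PolarizedVariant(position, ancestral=ref, derived=alt, k=alt_count, n=n)
    if outgroup_base == alt:
        return PolarizedVariant(position, ancestral=alt, derived=ref, k=ref_count, n=n)
    return None


def classify_genomic(
    genome: str,
    cds_start: int,
    cds_end: int,
    strand: str,
    position: int,
    alt: str,
    table_id: int = 1,
) -> str:
    """Classify a genome-coordinate variant inside a CDS, strand-aware.

    The codon is always read in transcript orientation, so the call is invariant
    under reverse-complementing the genome (with mirrored coordinates).
    """
    if not cds_start <= position < cds_end:
        raise ValueError("variant outside the CDS span")
    if strand == "+":
        tpos = position - cds_start
        transcript = genome[cds_start:cds_end]
        talt = alt
    elif strand == "-":
        tpos = cds_end - 1 - position
        transcript = reverse_complement(genome[cds_start:cds_end])
        talt = reverse_complement(alt)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    codon = transcript[3 * (tpos // 3) : 3 * (tpos // 3) + 3]
    return classify_variant(codon, tpos % 3, talt, table_id)


def nonsyn_lookup(cds: str, table_id: int = 1):
    """Per-position, per-alt nonsynonymous indicator for a coding sequence.

    Returns a dict-free compact structure: list of length ``len(cds)`` where entry
    ``p`` maps each alt base (the 3 non-reference bases) to True if nonsynonymous.
    Used by the forward simulator for O(1) classification of arising mutations.
    """
    cds = cds.upper()
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        out.extend(_codon_lookup(cds[i : i + 3], table_id))
    for p in range(len(cds) - len(cds) % 3, len(cds)):  # trailing partial codon
        out.append({})
    return out


@lru_cache(maxsize=None)
def _codon_lookup(codon: str, table_id: int) -> tuple:
    entries = []
    for offset in range(3):
        entry = {}
        for b in BASES:
            if b == codon[offset]:
                continue
            entry[b] = classify_variant(codon, offset, b, table_id) == NONSYNONYMOUS
        entries.append(entry)
    return tuple(entries)
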