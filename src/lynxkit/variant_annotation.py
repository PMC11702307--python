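"""Coding-variant calling and consequence annotation against a reference CDS.

Targeted Sanger sequencing of a gene's coding exons yields one consensus
sequence per sample, with heterozygous positions represented as IUPAC
ambiguity codes (e.g. a C/T heterozygote reads ``Y``).  This module aligns
such sample sequences to the reference CDS with a deterministic global
(Needleman–Wunsch) aligner, calls substitutions and indels, classifies
their protein consequence (synonymous / missense / nonsense / frameshift /
in-frame indel) under the standard genetic code, and maps full-length
(preprotein) residue numbers to mature-protein numbering by subtracting
the signal-peptide length — e.g. a substitution at residue 61 of the
LYNX2 preprotein is residue 39 of the mature, signal-cleaved protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "CodingVariant",
    "Alignment",
    "SIGNAL_PEPTIDE",
    "IUPAC_CODES",
    "read_fasta",
    "write_fasta",
    "expand_iupac",
    "align_to_reference",
    "call_variants",
    "map_to_mature",
    "tally_carriers",
]

IUPAC_CODES = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Sentinel returned by :func:`map_to_mature` for positions inside the
#: signal peptide, which is cleaved from the mature protein.
SIGNAL_PEPTIDE = "signal_peptide"

# Needleman-Wunsch scoring (affine gaps): opening a gap costs GAP_OPEN,
# each additional gapped column costs GAP_EXTEND.
MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0


@dataclass(frozen=True)
class GeneModel:
    """A coding sequence with signal-peptide annotation.

    ``signal_peptide_length`` (residues) offsets full-length versus mature
    protein numbering; the default 22 matches LYNX2, whose preprotein
    residue 61 is mature residue 39.
    """

    cds_sequence: str
    signal_peptide_length: int = 22
    exon_boundaries: tuple = ()  # informational CDS offsets
    gene: str = "LYNX2"
    protein: str = "LYNX2"

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if len(seq) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not seq.startswith("ATG"):
            raise ValueError("CDS must start with ATG")
        if set(seq) - set("ACGT"):
            raise ValueError("reference CDS must be unambiguous A/C/G/T")
        if not 0 <= self.signal_peptide_length < len(seq) // 3:
            raise ValueError("signal peptide must be shorter than the protein")

    @property
    def protein_length(self) -> int:
        return len(self.cds_sequence) // 3

    def codon(self, codon_index: int) -> str:
        """1-based codon lookup."""
        if not 1 <= codon_index <= self.protein_length:
            raise ValueError(f"codon index {codon_index} out of range")
        return self.cds_sequence[3 * (codon_index - 1) : 3 * codon_index]


@dataclass(frozen=True)
class CodingVariant:
    """One called coding change with dual full-length/mature coordinates."""

    cds_position: int  # 1-based
    ref: str
    alt: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    full_length_position: int
    mature_position: int | str  # int, or SIGNAL_PEPTIDE flag
    consequence: str  # synonymous | missense | nonsense | frameshift | inframe_indel
    zygosity: str  # het | hom

    @property
    def aa_change_full(self) -> str:
        if self.consequence == "frameshift":
            return f"{self.ref_aa}{self.full_length_position}fs"
        return f"{self.ref_aa}{self.full_length_position}{self.alt_aa}"

    @property
    def aa_change_mature(self) -> str | None:
        if self.mature_position == SIGNAL_PEPTIDE:
            return None
        if self.consequence == "frameshift":
            return f"{self.ref_aa}{self.mature_position}fs"
        return f"{self.ref_aa}{self.mature_position}{self.alt_aa}"


def read_fasta(path) -> dict:
    """Read FASTA into an ordered {id: uppercase sequence} mapping.

    Rejects duplicate ids and non-IUPAC characters (``-`` gaps excluded).
    """
    records: dict = {}
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = set(seq) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"non-IUPAC characters in {rec.id!r}: {sorted(bad)}")
            records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict, path) -> None:
    """Write {id: sequence} to FASTA (uppercase, 60-column wrapping)."""
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def expand_iupac(base: str) -> frozenset:
    """Expand one IUPAC nucleotide symbol into its allele set."""
    try:
        return IUPAC_CODES[base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol {base!r}") from None


@dataclass(frozen=True)
class Alignment:
    """Global pairwise alignment of a sample against the reference."""

    aligned_reference: str
    aligned_sample: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_reference) != len(self.aligned_sample):
            raise ValueError("aligned strings must have equal length")


def align_to_reference(sample: str, reference: str) -> Alignment:
    """Needleman–Wunsch global alignment with deterministic traceback.

    Scores: match +1, mismatch −1, gap open −4, gap extend −1 (affine;
    opening a gap of length L costs 4 + (L−1)).  IUPAC-ambiguous sample
    bases count as a match when the reference allele is in their expansion.
    Traceback ties prefer diagonal, then the vertical (gap-in-sample) move,
    giving a unique alignment.
    """
    s = sample.upper()
    r = reference.upper()
    if not s or not r:
        raise ValueError("sequences must be non-empty")
    n, m = len(r), len(s)  # rows: reference, cols: sample
    neg = -math.inf
    # Gotoh three-matrix recursion. M: match/mismatch end, X: gap in sample
    # (reference base unmatched, vertical), Y: gap in reference (horizontal).
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        ri = r[i - 1]
        for j in range(1, m + 1):
            sj = s[j - 1]
            sub = MATCH if ri in expand_iupac(sj) else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + sub
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND,
                          X[i, j - 1] + GAP_OPEN)

    # traceback, preferring diagonal, then vertical (up), then horizontal
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda k: {"M": M, "X": X, "Y": Y}[k][n, m])
    score = {"M": M, "X": X, "Y": Y}[state][n, m]
    out_r, out_s = [], []
    while i > 0 or j > 0:
        if state == "M":
            out_r.append(r[i - 1])
            out_s.append(s[j - 1])
            sub = MATCH if r[i - 1] in expand_iupac(s[j - 1]) else MISMATCH
            target = M[i, j] - sub
            i, j = i - 1, j - 1
            for k, mat in (("M", M), ("X", X), ("Y", Y)):
                if math.isclose(mat[i, j], target, rel_tol=0.0, abs_tol=1e-9):
                    state = k
                    break
        elif state == "X":
            out_r.append(r[i - 1])
            out_s.append("-")
            here = X[i, j]
            i -= 1
            if math.isclose(M[i, j] + GAP_OPEN, here, abs_tol=1e-9):
                state = "M"
            elif math.isclose(X[i, j] + GAP_EXTEND, here, abs_tol=1e-9):
                state = "X"
            else:
                state = "Y"
        else:  # Y: gap in reference
            out_r.append("-")
            out_s.append(s[j - 1])
            here = Y[i, j]
            j -= 1
            if math.isclose(M[i, j] + GAP_OPEN, here, abs_tol=1e-9):
                state = "M"
            elif math.isclose(Y[i, j] + GAP_EXTEND, here, abs_tol=1e-9):
                state = "Y"
            else:
                state = "X"
        if i == 0 and j == 0:
            break
    return Alignment("".join(reversed(out_r)), "".join(reversed(out_s)), float(score))


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _classify_substitution(ref_aa: str, alt_aa: str) -> str:
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"


def map_to_mature(full_length_position: int, signal_peptide_length: int):
    """Convert full-length (preprotein) residue numbering to mature numbering.

    Residues at or before the signal-peptide cleavage point return the
    :data:`SIGNAL_PEPTIDE` flag instead of a number.
    """
    if full_length_position < 1 or signal_peptide_length < 0:
        raise ValueError("positions must be positive")
    if full_length_position <= signal_peptide_length:
        return SIGNAL_PEPTIDE
    return full_length_position - signal_peptide_length


def call_variants(alignment: Alignment, gene_model: GeneModel) -> list:
    """Call coding variants from a sample/reference alignment.

    Substitution columns are compared codon-wise, with IUPAC ambiguity
    codes expanded: the call is heterozygous when the reference allele is
    inside the expanded set alongside a differing alternative allele.
    Indels whose length is not a multiple of 3 are frameshifts, annotated
    at the first shifted codon; in-frame indels are reported as
    ``inframe_indel``.  Amino-acid labels use full-length coordinates with
    a parallel mature-coordinate annotation.
    """
    ref_ungapped = alignment.aligned_reference.replace("-", "")
    if ref_ungapped != gene_model.cds_sequence:
        raise ValueError("alignment reference does not match the gene model CDS")

    variants = []
    ref_pos = 0
    col = 0
    cols = len(alignment.aligned_reference)
    while col < cols:
        rb = alignment.aligned_reference[col]
        sb = alignment.aligned_sample[col]
        if rb != "-" and sb != "-":
            ref_pos += 1
            if sb != rb:
                alleles = expand_iupac(sb)
                if alleles == {rb}:
                    col += 1
                    continue
                if rb in alleles:
                    zygosity = "het"
                    alts = sorted(alleles - {rb})
                else:
                    zygosity = "hom" if len(alleles) == 1 else "het"
                    alts = sorted(alleles)
                alt = alts[0]
                codon_index = math.ceil(ref_pos / 3)
                ref_codon = gene_model.codon(codon_index)
                offset = (ref_pos - 1) % 3
                alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1 :]
                ref_aa = _translate(ref_codon)
                alt_aa = _translate(alt_codon)
                variants.append(
                    CodingVariant(
                        cds_position=ref_pos,
                        ref=rb,
                        alt=alt,
                        codon_index=codon_index,
                        ref_codon=ref_codon,
                        alt_codon=alt_codon,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        full_length_position=codon_index,
                        mature_position=map_to_mature(
                            codon_index, gene_model.signal_peptide_length
                        ),
                        consequence=_classify_substitution(ref_aa, alt_aa),
                        zygosity=zygosity,
                    )
                )
            col += 1
        else:
            # a gap run: deletion (gap in sample) or insertion (gap in reference)
            run_start = col
            gap_in_sample = sb == "-"
            while col < cols:
                rb2 = alignment.aligned_reference[col]
                sb2 = alignment.aligned_sample[col]
                if gap_in_sample and sb2 == "-" and rb2 != "-":
                    col += 1
                elif not gap_in_sample and rb2 == "-" and sb2 != "-":
                    col += 1
                else:
                    break
            run_len = col - run_start
            if gap_in_sample:
                deleted = alignment.aligned_reference[run_start:col]
                anchor = ref_pos + 1
                ref_pos += run_len
                ref_allele, alt_allele = deleted, ""
            else:
                inserted = alignment.aligned_sample[run_start:col]
                anchor = ref_pos + 1 if ref_pos < len(ref_ungapped) else ref_pos
                ref_allele, alt_allele = "", inserted
            codon_index = math.ceil(anchor / 3)
            codon_index = min(codon_index, gene_model.protein_length)
            ref_codon = gene_model.codon(codon_index)
            ref_aa = _translate(ref_codon)
            consequence = "frameshift" if run_len % 3 else "inframe_indel"
            variants.append(
                CodingVariant(
                    cds_position=anchor,
                    ref=ref_allele,
                    alt=alt_allele,
                    codon_index=codon_index,
                    ref_codon=ref_codon,
                    alt_codon="",
                    ref_aa=ref_aa,
                    alt_aa="fs" if consequence == "frameshift" else "del/ins",
                    full_length_position=codon_index,
                    mature_position=map_to_mature(
                        codon_index, gene_model.signal_peptide_length
                    ),
                    consequence=consequence,
                    zygosity="hom",
                )
            )
    variants.sort(key=lambda v: v.cds_position)
    return variants


def tally_carriers(
    calls: pd.DataFrame,
    total_n: int,
    exclusively_heterozygous=(),
) -> pd.DataFrame:
    """Per-variant carrier counts, percentages and zygosity breakdown.

    ``calls`` needs columns participant_id, variant (a label such as
    "Q61H"), zygosity.  Percentages are of ``total_n`` and reported to one
    decimal.  Variants named in ``exclusively_heterozygous`` are flagged if
    any homozygous call appears.
    """
    required = {"participant_id", "variant", "zygosity"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    if calls.duplicated(["participant_id", "variant"]).any():
        raise ValueError("duplicate participant/variant rows")
    if total_n < calls["participant_id"].nunique():
        raise ValueError("total_n smaller than the number of carriers")
    rows = []
    for variant, grp in calls.groupby("variant", sort=True):
        n = int(grp["participant_id"].nunique())
        het = int((grp["zygosity"] == "het").sum())
        hom = int((grp["zygosity"] == "hom").sum())
        rows.append({
            "variant": variant,
            "carriers": n,
            "total_n": total_n,
            "percent": round(100.0 * n / total_n, 1),
            "het": het,
            "hom": hom,
            "zygosity_flag": bool(variant in set(exclusively_heterozygous) and hom > 0),
        })
    return pd.DataFrame(rows)
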