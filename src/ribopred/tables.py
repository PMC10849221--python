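"""Packaged reference tables for codon, tRNA and protein-stability features.

Everything here is an overridable default: functions that consume these
tables accept user-supplied replacements (e.g. tRNA gene-copy numbers for a
different strain, or an alternative wobble-penalty set).
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

# Bacterial/plastid genetic code. Built once from Biopython's table 11.
_TABLE11 = unambiguous_dna_by_id[11]

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
START_CODONS = ("ATG", "CTG", "GTG", "TTG")

#: codon -> single-letter amino acid, 61 sense codons (table 11 sense set
#: restricted to the canonical 61; table 11 lists extra start codons but the
#: forward table is the standard one).
CODON_TO_AA: dict[str, str] = {
    c: aa for c, aa in _TABLE11.forward_table.items() if c not in STOP_CODONS
}

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _c, _aa in CODON_TO_AA.items():
    SYNONYMOUS.setdefault(_aa, ())
    SYNONYMOUS[_aa] = SYNONYMOUS[_aa] + (_c,)

# ---------------------------------------------------------------------------
# tRNA adaptation index defaults
# ---------------------------------------------------------------------------

#: E. coli K-12 tRNA gene copy numbers by anticodon (5'->3').  Values follow
#: the commonly used genomic tRNA census for K-12 MG1655; they are defaults,
#: not measurements made here, and can be overridden per organism.
ECOLI_TRNA_COPIES: dict[str, int] = {
    # Ala
    "TGC": 3, "GGC": 2,
    # Arg
    "ACG": 4, "CCG": 1, "TCT": 1, "CCT": 1,
    # Asn
    "GTT": 4,
    # Asp
    "GTC": 3,
    # Cys
    "GCA": 1,
    # Gln
    "TTG": 2, "CTG": 2,
    # Glu
    "TTC": 4,
    # Gly
    "GCC": 4, "TCC": 1, "CCC": 1,
    # His
    "GTG": 1,
    # Ile (CAT here is the lysidine-modified AUA reader)
    "GAT": 3, "CAT": 1,
    # Leu
    "CAG": 4, "GAG": 1, "TAG": 1, "CAA": 1, "TAA": 1,
    # Lys
    "TTT": 6,
    # Met (elongator)
    "CAT_MET": 4,
    # Phe
    "GAA": 2,
    # Pro
    "CGG": 1, "GGG": 1, "TGG": 1,
    # Ser
    "GGA": 2, "TGA": 1, "CGA": 1, "GCT": 1,
    # Thr
    "GGT": 2, "CGT": 1, "TGT": 1,
    # Trp
    "CCA": 1,
    # Tyr
    "GTA": 3,
    # Val
    "GAC": 2, "TAC": 2,
}

#: Wobble-pairing selective penalties s (codon 3rd base : anticodon 1st
#: base), the standard non-optimised set of the tAI literature.  A penalty of
#: 0 means Watson-Crick decoding; values near 1 mean the pairing barely
#: contributes.
DEFAULT_S_VALUES: dict[str, float] = {
    "T:A": 0.0,      # Watson-Crick
    "C:G": 0.0,
    "A:T": 0.0,
    "G:C": 0.0,
    "T:G": 0.41,     # G34 reading U-ending codons
    "C:A": 0.28,     # inosine (from A34) reading C
    "A:A": 0.9999,   # inosine reading A
    "G:T": 0.68,     # U34 reading G-ending codons
    "A:C": 0.89,     # lysidine-modified C34 reading AUA
}

# ---------------------------------------------------------------------------
# Protein stability defaults
# ---------------------------------------------------------------------------

#: Bacterial N-end rule: destabilising N-terminal residues confer an in-vivo
#: half-life of under two minutes; everything else is long-lived (>10 h).
#: Proline is unclassifiable by the rule alone and is excluded.
NEND_DESTABILIZING = frozenset("LFWYRK")

#: Residues small enough for methionine aminopeptidase to cleave the
#: initiator Met when they occupy position 2.
MET_EXCISION_RESIDUES = frozenset("ACGPSTV")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def default_dwell_times(mean_dwell: float = 0.05,
                        adaptiveness_floor: float = 0.25,
                        trna_copies: dict[str, int] | None = None,
                        s_values: dict[str, float] | None = None,
                        ) -> dict[str, float]:
    """Per-codon ribosome dwell times (s) derived from tRNA availability.

    Dwell time is taken proportional to 1/(w + floor), where w is the
    codon's relative tAI adaptiveness, then rescaled so the mean over the
    61 sense codons equals ``mean_dwell`` seconds (a typical bacterial
    decoding time of ~0.05 s/codon at fast growth).  The floor keeps the
    per-codon speed range within the modest (~5-fold) spread seen in
    ribosome-profiling dwell estimates rather than letting near-zero
    adaptiveness values imply arbitrarily slow codons; gene-aggregate
    elongation rates then vary by only tens of percent across genes.
    """
    from .features import tai_weights  # local import to avoid cycle

    w = tai_weights(trna_copies=trna_copies, s_values=s_values)
    raw = {c: 1.0 / (w[c] + adaptiveness_floor) for c in SENSE_CODONS}
    mean_raw = sum(raw.values()) / len(raw)
    scale = mean_dwell / mean_raw
    return {c: v * scale for c, v in raw.items()}
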