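"""Sequence- and protein-derived predictors of protein expression.

The eleven model features carried by :class:`FeatureVector` are, by their
canonical table names:

==============  ==========================================================
Type            first gene of its operon (bool)
uAUG            upstream AUG class in the -12..-1 window (none/in/out of frame)
Start           start codon identity (ATG/GTG/TTG/CTG)
Stop            stop codon identity (TAA/TGA/TAG)
CAI             codon adaptation index (geometric mean of relative
                synonymous-codon adaptiveness)
tAI             tRNA adaptation index (tRNA-availability weighted analogue)
MFE_p1_p30      folding energy of the +1..+30 window, kcal/mol
Length          protein length, amino acids
Nend            N-end-rule half-life class (>10 h / <2 min / Pro excluded)
Instability     Guruprasad instability index
New_TR          learned translation rate (filled by the ML stage)
==============  ==========================================================

plus the three mechanistic rates (InitRate, ElongRate, TransimTR) computed
by :mod:`ribopred.translation`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV

from . import folding
from .sequence_io import GeneRecord
from .tables import (
    CODON_TO_AA,
    DEFAULT_S_VALUES,
    ECOLI_TRNA_COPIES,
    MET_EXCISION_RESIDUES,
    NEND_DESTABILIZING,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS,
)

__all__ = [
    "UaugClass",
    "NEndClass",
    "FeatureVector",
    "classify_uaug",
    "start_codon_type",
    "stop_codon_type",
    "build_cai_weights",
    "compute_cai",
    "tai_weights",
    "compute_tai",
    "n_end_half_life",
    "instability_index",
    "nucleotide_frequency_matrix",
    "build_feature_table",
    "CATEGORICAL_FEATURES",
    "OPTIONAL_FEATURES",
]


class UaugClass(str, Enum):
    NONE = "NONE"
    IN_FRAME = "IN_FRAME"
    OUT_OF_FRAME = "OUT_OF_FRAME"


class NEndClass(str, Enum):
    STABLE_GT_10H = "STABLE_GT_10H"
    UNSTABLE_LT_2MIN = "UNSTABLE_LT_2MIN"
    EXCLUDED_PRO = "EXCLUDED_PRO"


@dataclass
class FeatureVector:
    """The named predictors for one gene (None marks a missing value)."""

    gene_id: str
    type_first_gene: bool
    uaug_class: UaugClass
    start_codon: str
    stop_codon: str
    cai: float
    tai: float
    mfe_plus1_plus30: float | None
    length: int
    n_end_class: NEndClass
    instability_index: float
    initiation_rate: float | None = None
    elongation_rate: float | None = None
    transim_translation_rate: float | None = None
    new_tr: float | None = None


def classify_uaug(utr5: str, window_len: int = 12) -> UaugClass:
    """Classify upstream AUGs in the ``-window_len..-1`` window.

    An upstream ATG starting at position -p (p >= 3, so the triplet lies
    wholly in the UTR) is in frame with the main ORF iff p is a multiple of
    3.  If both frames occur, IN_FRAME wins; with no upstream ATG the class
    is NONE.  A UTR shorter than the window is scanned as far as it exists.
    """
    utr5 = utr5.upper().replace("U", "T")
    scan = utr5[-window_len:] if window_len < len(utr5) else utr5
    found_out = False
    n = len(scan)
    for i in range(0, n - 2):
        if scan[i:i + 3] == "ATG":
            offset = n - i  # uATG start position is -offset
            if offset % 3 == 0:
                return UaugClass.IN_FRAME
            found_out = True
    return UaugClass.OUT_OF_FRAME if found_out else UaugClass.NONE


def start_codon_type(cds: str) -> str:
    codon = cds[:3].upper()
    if codon not in ("ATG", "GTG", "TTG", "CTG"):
        raise ValueError(f"not a recognised start codon: {codon}")
    return codon


def stop_codon_type(cds: str) -> str:
    codon = cds[-3:].upper()
    if codon not in STOP_CODONS:
        raise ValueError(f"terminal codon {codon} is not a stop codon")
    return codon


def _body_codons(cds: str) -> list[str]:
    """Codons 2..L-1: initiator and terminal stop excluded."""
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    return codons[1:-1]


def build_cai_weights(
    reference_cds: Iterable[str], pseudo_count: float = 0.5
) -> dict[str, float]:
    """Relative synonymous-codon adaptiveness from a reference CDS set.

    For each amino acid, weight(codon) = count / max count among synonyms,
    counting body codons only (initiator and stop excluded).  Codons unseen
    in the reference receive ``pseudo_count`` occurrences before division.
    Amino acids wholly absent from the reference get neutral weight 1 for
    all their codons, with a warning.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    any_ref = False
    for cds in reference_cds:
        any_ref = True
        for codon in _body_codons(cds.upper()):
            if codon in counts:
                counts[codon] += 1
    if not any_ref:
        raise ValueError("empty reference set")
    weights: dict[str, float] = {}
    for aa, codons in SYNONYMOUS.items():
        family = {c: counts[c] if counts[c] > 0 else pseudo_count for c in codons}
        mx = max(family.values())
        if all(counts[c] == 0 for c in codons):
            warnings.warn(
                f"amino acid {aa} absent from CAI reference; "
                "its codons get neutral weight 1"
            )
            for c in codons:
                weights[c] = 1.0
        else:
            for c in codons:
                weights[c] = family[c] / mx
    return weights


def compute_cai(cds: str, weights: Mapping[str, float]) -> float:
    """Geometric mean of codon weights over the gene body (codons 2..L-1)."""
    body = _body_codons(cds.upper())
    if not body:
        raise ValueError("CDS has no body codons between start and stop")
    log_sum = 0.0
    for codon in body:
        w = weights.get(codon)
        if w is None or w <= 0:
            raise ValueError(f"no positive weight for codon {codon}")
        log_sum += math.log(w)
    return math.exp(log_sum / len(body))


# --- tAI -------------------------------------------------------------------

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_WC[c] for c in reversed(seq))


def tai_weights(
    trna_copies: Mapping[str, float] | None = None,
    s_values: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Relative tAI adaptiveness w(codon) for the 61 sense codons.

    Absolute adaptiveness W(codon) sums (1 - s) * gene copies over the
    anticodons that can decode the codon: the Watson-Crick anticodon plus
    the standard wobble reader determined by the codon's third base
    (G34 for U-ending, inosine for C/A-ending, U34 for G-ending codons).
    AUG and AUA are special-cased: the elongator-Met anticodon is keyed
    ``CAT_MET`` in the copy table and the lysidine-modified AUA reader is
    keyed ``CAT``.  Relative w = W / max W; codons with W = 0 receive the
    geometric mean of the nonzero w values.
    """
    copies = dict(ECOLI_TRNA_COPIES if trna_copies is None else trna_copies)
    s = dict(DEFAULT_S_VALUES)
    if s_values is not None:
        s.update(s_values)

    def cp(anticodon: str) -> float:
        return float(copies.get(anticodon, 0.0))

    W: dict[str, float] = {}
    for codon in SENSE_CODONS:
        third = codon[2]
        wc_anti = _revcomp(codon)
        if codon == "ATG":
            W[codon] = (1 - s["G:C"]) * cp("CAT_MET")
            continue
        if codon == "ATA":
            # U34 reader TAT is absent in E. coli; decoding is via the
            # lysidine-modified CAU anticodon.
            w = (1 - s["A:T"]) * cp("TAT") + (1 - s["A:C"]) * cp("CAT")
            W[codon] = w
            continue
        if third == "T":
            w = (1 - s["T:A"]) * cp(wc_anti)
            w += (1 - s["T:G"]) * cp("G" + wc_anti[1:])
        elif third == "C":
            w = (1 - s["C:G"]) * cp(wc_anti)
            w += (1 - s["C:A"]) * cp("A" + wc_anti[1:])
        elif third == "A":
            w = (1 - s["A:T"]) * cp(wc_anti)
            w += (1 - s["A:A"]) * cp("A" + wc_anti[1:])
        else:  # G-ending
            w = (1 - s["G:C"]) * cp(wc_anti)
            w += (1 - s["G:T"]) * cp("T" + wc_anti[1:])
        W[codon] = w

    mx = max(W.values())
    if mx <= 0:
        raise ValueError("all-zero tRNA adaptiveness: check the copy table")
    w_rel = {c: W[c] / mx for c in W}
    nonzero = [v for v in w_rel.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    return {c: (v if v > 0 else gm) for c, v in w_rel.items()}


def compute_tai(
    cds: str,
    trna_copies: Mapping[str, float] | None = None,
    s_values: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
) -> float:
    """tRNA adaptation index: geometric mean of tAI weights over the gene
    body.  Precomputed ``weights`` (from :func:`tai_weights`) short-circuit
    the table work when scoring many genes."""
    if weights is None:
        weights = tai_weights(trna_copies=trna_copies, s_values=s_values)
    body = _body_codons(cds.upper())
    if not body:
        raise ValueError("CDS has no body codons between start and stop")
    log_sum = 0.0
    for codon in body:
        w = weights.get(codon)
        if w is None or w <= 0:
            raise ValueError(f"no positive tAI weight for codon {codon}")
        log_sum += math.log(w)
    return math.exp(log_sum / len(body))


# --- protein stability -----------------------------------------------------


def n_end_half_life(protein: str, met_excision: bool = True) -> NEndClass:
    """Classify a protein's half-life by the bacterial N-end rule.

    The classified residue is residue 2 when methionine aminopeptidase would
    excise the initiator Met (residue 2 in {A,C,G,P,S,T,V}) and
    ``met_excision`` is enabled; otherwise the retained Met (residue 1).
    Destabilising residues (L,F,W,Y,R,K) mean a half-life under two minutes;
    Proline is unclassifiable and excluded; everything else exceeds 10 h.
    """
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein")
    residue = protein[0]
    if met_excision and len(protein) >= 2 and protein[1] in MET_EXCISION_RESIDUES:
        residue = protein[1]
    if residue == "P":
        return NEndClass.EXCLUDED_PRO
    if residue in NEND_DESTABILIZING:
        return NEndClass.UNSTABLE_LT_2MIN
    return NEndClass.STABLE_GT_10H


def instability_index(protein: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide instability
    weights over consecutive residue pairs.  Values above 40 predict an
    unstable protein in vitro."""
    protein = protein.upper()
    L = len(protein)
    if L < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = 0.0
    for i in range(L - 1):
        a, b = protein[i], protein[i + 1]
        try:
            total += DIWV[a][b]
        except KeyError:
            raise ValueError(f"unknown residue in dipeptide {a}{b}") from None
    return total * 10.0 / L


# --- positional composition ------------------------------------------------


def nucleotide_frequency_matrix(
    records: Sequence[GeneRecord], window: tuple[int, int] = (-15, 15)
) -> pd.DataFrame:
    """Per-position nucleotide frequencies around the start codon.

    Rows are coordinate positions (no position 0), columns A/C/G/T.
    Frequencies at each position are computed over the records whose
    sequence covers that position; covered rows sum to 1, uncovered rows
    are NaN.
    """
    if not records:
        raise ValueError("no records")
    positions = [p for p in range(window[0], window[1] + 1) if p != 0]
    counts = pd.DataFrame(0.0, index=positions, columns=list("ACGT"))
    coverage = pd.Series(0, index=positions, dtype=float)
    for rec in records:
        for pos in positions:
            if pos < 0:
                idx = len(rec.utr5) + pos
                base = rec.utr5[idx] if idx >= 0 else None
            else:
                base = rec.cds[pos - 1] if pos - 1 < len(rec.cds) else None
            if base in ("A", "C", "G", "T"):
                counts.loc[pos, base] += 1
                coverage[pos] += 1
    freq = counts.div(coverage, axis=0)
    return freq


# --- feature table ---------------------------------------------------------

#: Features that enter the model as one-hot blocks.
CATEGORICAL_FEATURES = ("Type", "uAUG", "Start", "Stop", "Nend")

#: The ten optional features combinable with New_TR in the subset search.
OPTIONAL_FEATURES = (
    "Type", "uAUG", "Start", "Stop", "CAI", "tAI",
    "MFE_p1_p30", "Length", "Nend", "Instability",
)

#: Candidate start-anchored folding windows screened by the missing-data
#: rule; only those with an acceptable missing fraction become features.
DEFAULT_MFE_WINDOWS: dict[str, tuple[int, int]] = {
    "MFE_m30_m1": (-30, -1),
    "MFE_p1_p30": (1, 30),
}


def extract_features(
    record: GeneRecord,
    cai_weights: Mapping[str, float],
    tai_w: Mapping[str, float],
    uaug_window: int = 12,
    folding_backend: str = "nussinov",
    mfe_windows: Mapping[str, tuple[int, int]] | None = None,
) -> dict[str, object]:
    """Raw (un-encoded) feature values for one gene."""
    windows = DEFAULT_MFE_WINDOWS if mfe_windows is None else mfe_windows
    row: dict[str, object] = {
        "gene_id": record.gene_id,
        "Type": bool(record.is_first_gene),
        "uAUG": classify_uaug(record.utr5, window_len=uaug_window).value,
        "Start": start_codon_type(record.cds),
        "Stop": stop_codon_type(record.cds),
        "CAI": compute_cai(record.cds, cai_weights),
        "tAI": compute_tai(record.cds, weights=tai_w),
        "Length": len(record.protein),
        "Nend": n_end_half_life(record.protein).value,
        "Instability": instability_index(record.protein),
    }
    for name, win in windows.items():
        row[name] = folding.folding_energy_window(
            record.utr5, record.cds, win, backend=folding_backend
        )
    return row


def feature_vector(
    record: GeneRecord,
    cai_weights: Mapping[str, float],
    tai_w: Mapping[str, float],
    **kwargs: object,
) -> FeatureVector:
    """Extract one gene's features as a typed :class:`FeatureVector`."""
    row = extract_features(record, cai_weights, tai_w, **kwargs)
    return FeatureVector(
        gene_id=record.gene_id,
        type_first_gene=bool(row["Type"]),
        uaug_class=UaugClass(row["uAUG"]),
        start_codon=str(row["Start"]),
        stop_codon=str(row["Stop"]),
        cai=float(row["CAI"]),
        tai=float(row["tAI"]),
        mfe_plus1_plus30=row.get("MFE_p1_p30"),
        length=int(row["Length"]),
        n_end_class=NEndClass(row["Nend"]),
        instability_index=float(row["Instability"]),
    )


def build_feature_table(
    records: Sequence[GeneRecord],
    rates: pd.DataFrame | None = None,
    responses: pd.DataFrame | None = None,
    missing_threshold: float = 0.15,
    cai_reference: Iterable[str] | None = None,
    trna_copies: Mapping[str, float] | None = None,
    uaug_window: int = 12,
    folding_backend: str = "nussinov",
    mfe_windows: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene feature table, applying the missing-data rule.

    ``rates`` (gene-indexed: initiation_rate, elongation_rate, and
    optionally translation_rate) and ``responses`` (pa, mrna, pa_per_mrna)
    are inner-joined on gene id when given.  A candidate folding-window
    feature whose missing fraction across the joined dataset exceeds
    ``missing_threshold`` is dropped entirely (never imputed); genes missing
    any retained numeric feature are then dropped.

    The CAI reference defaults to the input CDS set itself.
    """
    if not records:
        raise ValueError("no gene records")
    cai_ref = (
        [r.cds for r in records] if cai_reference is None else list(cai_reference)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cai_w = build_cai_weights(cai_ref)
    tai_w = tai_weights(trna_copies=trna_copies)

    rows = [
        extract_features(
            r, cai_w, tai_w,
            uaug_window=uaug_window,
            folding_backend=folding_backend,
            mfe_windows=mfe_windows,
        )
        for r in records
    ]
    table = pd.DataFrame(rows).set_index("gene_id")

    if rates is not None:
        table = table.join(rates, how="inner")
    if responses is not None:
        table = table.join(responses, how="inner")
    if table.empty:
        raise ValueError("empty joined feature table")

    windows = DEFAULT_MFE_WINDOWS if mfe_windows is None else mfe_windows
    for name in windows:
        missing_frac = table[name].isna().mean()
        if missing_frac > missing_threshold:
            table = table.drop(columns=[name])

    # Genes missing any retained numeric feature are dropped (and that is a
    # property of the gene, not of the feature set).
    table = table.dropna()
    if table.empty:
        raise ValueError("all genes dropped by the missing-data rule")
    return table


def one_hot_encode(
    table: pd.DataFrame, categorical: Sequence[str] = CATEGORICAL_FEATURES
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode categorical features, most frequent level as reference.

    Returns the encoded table and a map feature -> its encoded column block
    (numeric features map to themselves), so the subset search can keep
    blocks atomic.
    """
    blocks: dict[str, list[str]] = {}
    out = table.copy()
    for feat in table.columns:
        if feat in categorical:
            col = out[feat].astype(str)
            levels = col.value_counts()
            top = levels[levels == levels.max()].index
            reference = sorted(top)[0]  # deterministic tie-break
            cols = []
            for level in sorted(levels.index):
                if level == reference:
                    continue
                name = f"{feat}={level}"
                out[name] = (col == level).astype(float)
                cols.append(name)
            out = out.drop(columns=[feat])
            blocks[feat] = cols
        else:
            blocks[feat] = [feat]
    return out, blocks
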