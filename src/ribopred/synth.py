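"""Synthetic operon/expression generator.

Produces fixture genomes with the statistical structure the pipeline
assumes about real bacterial data — operons of one or more genes, A/G-rich
Shine-Dalgarno motifs a few nucleotides upstream of the start codon, A-rich
start context, codon-usage bias — together with expression tables carrying a
planted monotone dependence of protein abundance on chosen features plus
noise.  Replicate structure mirrors a two-condition, triplicate microarray
design.

Two expression modes:

* ``"planted"`` (default): log10 PA is a linear combination of standardized
  feature encodings plus Gaussian noise, so machine-learning recovery is
  analytically checkable.
* ``"mechanistic"``: log10 PA follows the TASEP simulator's translation
  rate times mRNA level, for end-to-end integration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import translation
from .sequence_io import GeneRecord, translate_cds
from .tables import SYNONYMOUS

__all__ = ["SynthConfig", "generate_genes", "generate_expression",
           "generate_dataset", "write_dataset"]

_START_CODONS = np.array(["ATG", "GTG", "TTG", "CTG"])
_START_PROBS = np.array([0.898, 0.060, 0.037, 0.005])
_STOP_CODONS = np.array(["TAA", "TGA", "TAG"])
_STOP_PROBS = np.array([0.697, 0.220, 0.083])
# A-rich background around bacterial start codons
_UTR_BASES = np.array(list("ATGC"))
_UTR_PROBS = np.array([0.45, 0.20, 0.20, 0.15])


def _default_effects() -> dict[str, float]:
    # Strong planted effects on the two mechanistic rates (so a learned
    # translation rate is recoverable: they carry ~90% of the signal
    # variance) plus moderate effects on four sequence features (so the
    # subset search has something to find beyond the learned rate).
    return {
        "initiation_rate": 1.0,
        "elongation_rate": 1.0,
        "Type": 0.2,
        "Start": 0.2,
        "Stop": 0.2,
        "Length": 0.2,
    }


@dataclass
class SynthConfig:
    """Study conditions of the synthetic genome/expression generator."""

    n_operons: int = 200
    genes_per_operon: float = 2.5      # geometric-distribution mean
    sd_strength: float = 0.8           # P(consensus AGGAGG upstream)
    codon_bias: float = 2.0            # exponential tilt toward adapted codons
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    noise_sd: float = 0.10             # log10 units on PA
    mrna_correlation: float = 0.6      # corr(log mRNA, log PA)
    mrna_sd: float = 0.4               # log10 spread of mRNA levels
    condition_sd: float = 0.10         # log10 condition effect on mRNA
    replicate_sd: float = 0.05         # log10 replicate noise
    utr_len: tuple[int, int] = (20, 40)
    cds_len: tuple[int, int] = (60, 900)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sd_strength <= 1:
            raise ValueError("sd_strength must be in [0, 1]")
        if self.n_operons < 1:
            raise ValueError("n_operons must be >= 1")


def _codon_sampler(bias: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-amino-acid synonymous codon distributions, tilted toward
    high-adaptiveness codons: P(codon) proportional to exp(bias * w_tai)."""
    w = feat.tai_weights()
    table = {}
    for aa, codons in SYNONYMOUS.items():
        cods = np.array(sorted(codons))
        logits = np.array([bias * w[c] for c in cods])
        p = np.exp(logits - logits.max())
        table[aa] = (cods, p / p.sum())
    return table


def _make_utr(rng: np.random.Generator, config: SynthConfig) -> str:
    n = int(rng.integers(config.utr_len[0], config.utr_len[1] + 1))
    utr = rng.choice(_UTR_BASES, size=n, p=_UTR_PROBS)
    if rng.random() < config.sd_strength:
        spacing = int(rng.integers(5, 8))  # SD 3' end 5-7 nt from the start
        start = n - spacing - 6
        if start >= 0:
            utr[start:start + 6] = list("AGGAGG")
    return "".join(utr)


def _make_cds(
    rng: np.random.Generator,
    config: SynthConfig,
    sampler: Mapping[str, tuple[np.ndarray, np.ndarray]],
    aa_pool: np.ndarray,
) -> str:
    lo, hi = config.cds_len
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    n_body = max(n_codons - 2, 1)
    start = rng.choice(_START_CODONS, p=_START_PROBS)
    stop = rng.choice(_STOP_CODONS, p=_STOP_PROBS)
    aas = rng.choice(aa_pool, size=n_body)
    body = np.empty(n_body, dtype=object)
    for aa in np.unique(aas):
        idx = np.nonzero(aas == aa)[0]
        cods, p = sampler[aa]
        body[idx] = rng.choice(cods, size=len(idx), p=p)
    return start + "".join(body) + stop


def generate_genes(
    config: SynthConfig,
) -> tuple[list[GeneRecord], dict[str, tuple[str, int, str]]]:
    """Generate operons of protein-coding genes with annotated 5'-UTRs.

    Every emitted record passes the protein-coding filters by construction
    (valid start/stop, length a multiple of 3, no internal stop).  Returns
    the records and the matching operon-annotation mapping
    ``gene_id -> (operon_id, position, utr5)``.
    """
    rng = np.random.default_rng(config.seed)
    sampler = _codon_sampler(config.codon_bias)
    aa_pool = np.array(sorted(SYNONYMOUS))
    records: list[GeneRecord] = []
    operon_table: dict[str, tuple[str, int, str]] = {}
    gene_no = 0
    for op in range(config.n_operons):
        operon_id = f"op{op + 1:04d}"
        size = int(rng.geometric(1.0 / max(config.genes_per_operon, 1.0)))
        for pos in range(1, size + 1):
            gene_no += 1
            gid = f"g{gene_no:05d}"
            utr = _make_utr(rng, config)
            cds = _make_cds(rng, config, sampler, aa_pool)
            records.append(
                GeneRecord(
                    gene_id=gid, utr5=utr, cds=cds,
                    protein=translate_cds(cds),
                    operon_id=operon_id, position_in_operon=pos,
                )
            )
            operon_table[gid] = (operon_id, pos, utr)
    return records, operon_table


# Monotone numeric encodings used to plant effects on categorical features.
_CATEGORY_SCORES: dict[str, dict[str, float]] = {
    "Start": {"ATG": 1.0, "GTG": 0.0, "TTG": -0.5, "CTG": -1.0},
    "Stop": {"TAA": 1.0, "TGA": 0.0, "TAG": -1.0},
    "uAUG": {"NONE": 1.0, "IN_FRAME": 0.0, "OUT_OF_FRAME": -1.0},
    "Nend": {"STABLE_GT_10H": 1.0, "EXCLUDED_PRO": 0.0,
             "UNSTABLE_LT_2MIN": -1.0},
}


def _encode_feature(
    name: str, records: Sequence[GeneRecord], rates: pd.DataFrame
) -> np.ndarray:
    if name == "initiation_rate":
        return np.log10(rates["initiation_rate"].to_numpy())
    if name == "elongation_rate":
        return rates["elongation_rate"].to_numpy()
    if name == "Type":
        return np.array([1.0 if r.is_first_gene else 0.0 for r in records])
    if name == "Length":
        return np.log10([len(r.protein) for r in records])
    if name == "Start":
        return np.array([_CATEGORY_SCORES["Start"][r.cds[:3]] for r in records])
    if name == "Stop":
        return np.array([_CATEGORY_SCORES["Stop"][r.cds[-3:]] for r in records])
    if name == "uAUG":
        return np.array(
            [_CATEGORY_SCORES["uAUG"][feat.classify_uaug(r.utr5).value]
             for r in records]
        )
    if name == "Nend":
        return np.array(
            [_CATEGORY_SCORES["Nend"][feat.n_end_half_life(r.protein).value]
             for r in records]
        )
    if name == "CAI":
        w = feat.build_cai_weights([r.cds for r in records])
        return np.array([feat.compute_cai(r.cds, w) for r in records])
    if name == "tAI":
        w = feat.tai_weights()
        return np.array([feat.compute_tai(r.cds, weights=w) for r in records])
    if name == "Instability":
        return np.array([feat.instability_index(r.protein) for r in records])
    if name == "MFE_p1_p30":
        return np.array(
            [feat.folding.folding_energy_window(r.utr5, r.cds, (1, 30))
             for r in records],
            dtype=float,
        )
    raise ValueError(f"no planted encoding for feature {name!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_expression(
    records: Sequence[GeneRecord],
    config: SynthConfig,
    rates: pd.DataFrame | None = None,
    mode: str = "planted",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Generate PA and replicate mRNA tables for the given genes.

    Returns ``(pa_table, mrna_table, grouping)``: a one-column protein
    abundance table, a 6-column mRNA table (3 replicates x 2 conditions)
    and the replicate-column -> condition mapping.

    In ``planted`` mode, log10 PA = sum of effect_sizes[f] * standardized
    feature encodings + Gaussian noise(noise_sd); mRNA is log-normal with a
    configurable correlation to PA.  In ``mechanistic`` mode, PA follows
    mRNA times the TASEP translation rate (``rates`` must then contain a
    ``translation_rate`` column).
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = [r.gene_id for r in records]
    if rates is None:
        rates, discarded = translation.compute_rate_profiles(
            records, simulate=(mode == "mechanistic"), seed=config.seed
        )
        if discarded:
            raise ValueError(
                "generator produced genes with too-short RBS "
                f"({len(discarded)}); widen utr_len"
            )
    rates = rates.loc[gene_ids]

    n = len(records)
    if mode == "planted":
        signal = np.zeros(n)
        for name, coef in config.effect_sizes.items():
            signal += coef * _zscore(_encode_feature(name, records, rates))
        log_pa = signal + rng.normal(0.0, config.noise_sd, size=n)
    elif mode == "mechanistic":
        if "translation_rate" not in rates:
            raise ValueError("mechanistic mode needs simulated rates")
        tr = rates["translation_rate"].to_numpy()
        log_pa = np.log10(tr + 1e-12) + rng.normal(0, config.noise_sd, n)
    else:
        raise ValueError(f"unknown expression mode {mode!r}")

    z_pa = _zscore(log_pa)
    rho = config.mrna_correlation
    log_mrna = config.mrna_sd * (
        rho * z_pa + math.sqrt(max(1 - rho ** 2, 0.0)) * rng.normal(size=n)
    ) + 2.0
    if mode == "mechanistic":
        # PA accumulates per transcript: scale protein level by mRNA.
        log_pa = log_pa + log_mrna

    pa_table = pd.DataFrame({"pa_integrated": 10.0 ** (log_pa + 2.0)},
                            index=pd.Index(gene_ids, name="gene_id"))

    grouping: dict[str, str] = {}
    mrna_cols = {}
    for cond in ("aerobic", "anaerobic"):
        cond_shift = rng.normal(0.0, config.condition_sd, size=n)
        for rep in (1, 2, 3):
            col = f"{cond}_r{rep}"
            noise = rng.normal(0.0, config.replicate_sd, size=n)
            mrna_cols[col] = 10.0 ** (log_mrna + cond_shift + noise)
            grouping[col] = cond
    mrna_table = pd.DataFrame(mrna_cols, index=pd.Index(gene_ids, name="gene_id"))
    return pa_table, mrna_table, grouping


def generate_dataset(
    config: SynthConfig, mode: str = "planted"
) -> dict[str, object]:
    """Genes + operon table + expression tables in one call."""
    records, operon_table = generate_genes(config)
    pa, mrna, grouping = generate_expression(records, config, mode=mode)
    return {
        "records": records,
        "operon_table": operon_table,
        "pa_table": pa,
        "mrna_table": mrna,
        "grouping": grouping,
    }


def write_dataset(config: SynthConfig, outdir: str | Path,
                  mode: str = "planted") -> dict[str, Path]:
    """Emit the generated dataset in the file dialects the pipeline reads:
    CDS FASTA, operon annotation TSV, PA TSV, replicate mRNA TSV and the
    replicate -> condition sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_dataset(config, mode=mode)
    paths = {
        "cds_fasta": outdir / "cds.fasta",
        "operons": outdir / "operons.tsv",
        "pa": outdir / "pa.tsv",
        "mrna": outdir / "mrna.tsv",
        "grouping": outdir / "replicate_conditions.tsv",
    }
    with open(paths["cds_fasta"], "w") as fh:
        for rec in data["records"]:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.cds), 70):
                fh.write(rec.cds[i:i + 70] + "\n")
    with open(paths["operons"], "w") as fh:
        fh.write("gene_id\toperon_id\tposition\tutr5\n")
        for gid, (op, pos, utr) in data["operon_table"].items():
            fh.write(f"{gid}\t{op}\t{pos}\t{utr}\n")
    data["pa_table"].to_csv(paths["pa"], sep="\t")
    data["mrna_table"].to_csv(paths["mrna"], sep="\t")
    with open(paths["grouping"], "w") as fh:
        fh.write("column\tcondition\n")
        for col, cond in data["grouping"].items():
            fh.write(f"{col}\t{cond}\n")
    return paths
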