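"""Biophysical translation-rate engine.

Three stages, mirroring how ribosome traffic on a bacterial mRNA is usually
modelled:

1. **Initiation rate** ``alpha`` from ribosome-binding-site energetics: the
   best hybridization of the 16S rRNA anti-Shine-Dalgarno tail
   (3'-UCCUCC-5') against the -20..-5 region, a quadratic penalty for
   non-optimal SD-to-start spacing, and the cost of unfolding mRNA
   structure around the start codon.  ``alpha = A_scale *
   exp(-dG_total/RT)``, with ``A_scale`` normalised so a perfect,
   unstructured SD at optimal spacing initiates at 1/s.
2. **Elongation rates** from per-codon dwell times (default: inverse tRNA
   adaptiveness scaled to a 0.05 s mean decoding time).
3. **TASEP simulation**: continuous-time kinetic Monte Carlo of an open 1-D
   lattice of codon sites with extended ribosomes (footprint ``ell``
   codons), giving the steady-state protein production flux, ribosome
   density profile, and jamming statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import folding
from .sequence_io import GeneRecord
from .tables import default_dwell_times

__all__ = [
    "InitiationParams",
    "RateProfile",
    "SimulationResult",
    "RbsTooShortError",
    "initiation_rate",
    "initiation_energy_breakdown",
    "elongation_rates",
    "tasep_simulate",
    "exact_steady_state",
    "transim_translation_rate",
    "compute_rate_profiles",
    "write_transim_input",
    "read_transim_input",
]

RBS_TOO_SHORT = "RBS_TOO_SHORT"


class RbsTooShortError(ValueError):
    """The 5'-UTR does not cover the anti-SD search window."""


# rRNA anti-SD tail 3'-UCCUCC-5'; written here as the bases met by the mRNA
# window read 5'->3'.
_ANTI_SD_TAIL = "UCCUCC"

# Per-pair hybridization pseudo-energies (kcal/mol) for the fallback
# match-count model: Watson-Crick G:C and A:U plus the G:U wobble.
_PAIR_DG = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}


@dataclass(frozen=True)
class InitiationParams:
    """Tunable constants of the initiation-energetics model."""

    rt: float = 0.6156                 # kcal/mol at 37 C
    search_window: tuple[int, int] = (-20, -5)
    optimal_spacing: int = 5           # nt between SD 3' end and start codon
    spacing_penalty: float = 0.1       # kcal/mol per nt^2 of misalignment
    unfold_window: tuple[int, int] = (-35, 35)
    # Coupling of the structure-opening cost.  The base-pair-count
    # pseudo-energy overstates how much of the window's structure the 30S
    # subunit must actually open, so the cost enters sub-unitarily; 0.1
    # places strong-SD genes near 0.01..1 /s and SD-less structured genes
    # near 1e-8..1e-3 /s, the two empirically observed clusters.
    unfold_weight: float = 0.1
    folding_backend: str = "nussinov"

    @property
    def perfect_duplex_energy(self) -> float:
        """dG of a full-length perfect SD/anti-SD duplex (AGGAGG:UCCUCC)."""
        return sum(_PAIR_DG[(b, t)] for b, t in zip("AGGAGG", _ANTI_SD_TAIL))

    @property
    def a_scale(self) -> float:
        """Pre-exponential factor: perfect unstructured SD gives alpha = 1/s."""
        return math.exp(self.perfect_duplex_energy / self.rt)


def _duplex_and_spacing(utr5: str, params: InitiationParams) -> float:
    """Best (most negative) hybridization + spacing energy over the search
    window, scanning every 6-nt placement inside it."""
    lo, hi = params.search_window
    tail_len = len(_ANTI_SD_TAIL)
    rna = utr5.upper().replace("T", "U")
    best = None
    # windows occupy positions p..p+5, fully inside [lo, hi]
    for p in range(lo, hi - tail_len + 2):
        window = []
        for pos in range(p, p + tail_len):
            idx = len(rna) + pos  # pos < 0
            window.append(rna[idx])
        dg = sum(
            _PAIR_DG.get((b, t), 0.0) for b, t in zip(window, _ANTI_SD_TAIL)
        )
        spacing = -(p + tail_len - 1) - 1  # nt between SD 3' end and +1
        dg += params.spacing_penalty * (spacing - params.optimal_spacing) ** 2
        if best is None or dg < best:
            best = dg
    return best


def initiation_energy_breakdown(
    utr5: str, cds: str, params: InitiationParams | None = None
) -> dict[str, float]:
    """Components of the total initiation energy (kcal/mol).

    Raises :class:`RbsTooShortError` when the UTR does not cover the anti-SD
    search window.  The unfold window is clipped to the available sequence
    (its cost is the negated fallback/thermodynamic MFE, i.e. >= 0).
    """
    params = params or InitiationParams()
    lo, _hi = params.search_window
    if len(utr5) < -lo:
        raise RbsTooShortError(
            f"UTR length {len(utr5)} < {-lo} nt anti-SD search window"
        )
    dg_duplex_spacing = _duplex_and_spacing(utr5, params)

    ulo, uhi = params.unfold_window
    ulo = max(ulo, -len(utr5))
    uhi = min(uhi, len(cds))
    seq = folding.window_sequence(utr5, cds, (ulo, uhi))
    mfe = folding.mfe(seq, backend=params.folding_backend) if seq else 0.0
    dg_unfold = max(0.0, -mfe) * params.unfold_weight

    total = dg_duplex_spacing + dg_unfold
    return {
        "dg_duplex_spacing": dg_duplex_spacing,
        "dg_unfold": dg_unfold,
        "dg_total": total,
    }


def initiation_rate(
    utr5: str, cds: str, params: InitiationParams | None = None
) -> float:
    """Translation initiation rate alpha (1/s) from RBS energetics."""
    params = params or InitiationParams()
    dg = initiation_energy_breakdown(utr5, cds, params)["dg_total"]
    return params.a_scale * math.exp(-dg / params.rt)


def elongation_rates(
    cds: str, dwell_table: Mapping[str, float] | None = None
) -> tuple[np.ndarray, float]:
    """Per-codon hop rates and the gene-aggregate elongation rate.

    The lattice covers the L sense codons of the CDS (terminal stop
    excluded).  Hop rate of codon i is 1/dwell(i); the gene rate is the
    harmonic-mean speed L / sum(dwell), codons per second.
    """
    if dwell_table is None:
        dwell_table = default_dwell_times()
    codons = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
    if not codons:
        raise ValueError("CDS has no sense codons")
    dwells = np.empty(len(codons))
    for i, c in enumerate(codons):
        d = dwell_table.get(c)
        if d is None or d <= 0:
            raise ValueError(f"non-positive or missing dwell time for {c}")
        dwells[i] = d
    hop_rates = 1.0 / dwells
    return hop_rates, len(codons) / dwells.sum()


@dataclass(frozen=True)
class RateProfile:
    """Kinetic parameters of one mRNA's translation."""

    gene_id: str
    alpha: float                    # initiation rate, 1/s
    hop_rates: np.ndarray           # per-codon elongation rates, 1/s
    beta: float = 10.0              # termination rate, 1/s (non-limiting)
    footprint: int = 10             # ribosome size, codons

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta <= 0 or self.footprint < 1:
            raise ValueError("rates must be positive and footprint >= 1")
        if len(self.hop_rates) < 1 or np.any(np.asarray(self.hop_rates) <= 0):
            raise ValueError("hop rates must be positive")


@dataclass(frozen=True)
class SimulationResult:
    """Steady-state output of one TASEP trajectory."""

    gene_id: str
    translation_rate: float         # proteins/s = terminations / t_measure
    density: np.ndarray             # per-site occupation probability
    terminations: int
    initiations: int
    collisions: float               # expected number of blocked hop attempts
    elapsed_model_time: float       # measurement window, s
    flux_se: float                  # split-half standard error of the flux
    converged: bool


@njit(cache=False)
def _tasep_kernel(L, ell, alpha, beta, k, t_burn, t_measure, seed):
    np.random.seed(seed)
    max_edge = L + ell - 1
    pos = np.zeros(L + 1, dtype=np.int64)  # sorted leading edges, pos[0:m]
    m = 0
    t = 0.0
    t_end = t_burn + t_measure
    half = t_burn + 0.5 * t_measure

    terminations = 0
    term_half1 = 0
    initiations = 0
    blocked_expect = 0.0
    density = np.zeros(L)
    rates = np.empty(L + 2)

    while t < t_end:
        # --- enumerate enabled events -----------------------------------
        init_ok = (m == 0) or (pos[0] >= 2 * ell)
        rates[0] = alpha if init_ok else 0.0
        total = rates[0]
        blocked_sum = 0.0
        for j in range(m):
            p = pos[j]
            if p == max_edge:
                r = beta
            elif j == m - 1 or pos[j + 1] - p > ell:
                a = p - ell  # 0-based A-site codon index
                if a < 0:
                    a = 0
                elif a > L - 1:
                    a = L - 1
                r = k[a]
            else:
                a = p - ell
                if a < 0:
                    a = 0
                elif a > L - 1:
                    a = L - 1
                blocked_sum += k[a]
                r = 0.0
            rates[j + 1] = r
            total += r
        if total <= 0.0:
            # absorbing empty system with alpha = 0: fast-forward
            t = t_end
            break
        dt = np.random.exponential(1.0 / total)
        t_next = t + dt
        # --- accumulate time-weighted statistics ------------------------
        w_lo = t if t > t_burn else t_burn
        w_hi = t_next if t_next < t_end else t_end
        if w_hi > w_lo:
            w = w_hi - w_lo
            blocked_expect += blocked_sum * w
            for j in range(m):
                p = pos[j]
                site_hi = p if p < L else L
                site_lo = p - ell + 1
                if site_lo < 1:
                    site_lo = 1
                for s in range(site_lo, site_hi + 1):
                    density[s - 1] += w
        # --- pick and apply the event -----------------------------------
        u = np.random.random() * total
        acc = rates[0]
        if u < acc:
            # initiation: new ribosome with leading edge ell
            for j in range(m, 0, -1):
                pos[j] = pos[j - 1]
            pos[0] = ell
            m += 1
            if t_next > t_burn:
                initiations += 1
        else:
            j = 0
            while j < m:
                acc += rates[j + 1]
                if u < acc:
                    break
                j += 1
            if j >= m:
                j = m - 1  # numerical guard
            if pos[j] == max_edge:
                m -= 1  # termination frees all sites (j == m-1)
                if t_next > t_burn:
                    terminations += 1
                    if t_next <= half:
                        term_half1 += 1
            else:
                pos[j] += 1
        t = t_next
    density /= t_measure
    return (terminations, term_half1, initiations, blocked_expect, density, m)


def tasep_simulate(
    profile: RateProfile,
    t_burn: float | None = None,
    t_measure: float | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Kinetic Monte Carlo simulation of ribosome traffic on one mRNA.

    Open-boundary TASEP with extended particles: a ribosome (footprint
    ``ell`` codons) loads at rate ``alpha`` when sites 1..ell are vacant,
    its leading edge hops forward at the A-site codon's elongation rate
    under hard-core exclusion (the front may slide past the lattice end),
    and it terminates at rate ``beta`` once the A-site reaches the last
    codon, freeing all its sites.

    Defaults: ``t_burn = 10 L / mean(k)``, ``t_measure = 50 L / mean(k)``.
    Statistics are collected only inside the measurement window; identical
    seeds give identical trajectories.  A warning (not a failure) is raised
    when split-half flux estimates differ by more than 3 combined standard
    errors.
    """
    k = np.ascontiguousarray(profile.hop_rates, dtype=np.float64)
    L = len(k)
    mean_k = float(k.mean())
    if t_burn is None:
        t_burn = 10.0 * L / mean_k
    if t_measure is None:
        t_measure = 50.0 * L / mean_k
    if t_burn <= 0 or t_measure <= 0:
        raise ValueError("t_burn and t_measure must be positive")

    terminations, term_half1, initiations, blocked, density, _m = _tasep_kernel(
        L, profile.footprint, float(profile.alpha), float(profile.beta),
        k, float(t_burn), float(t_measure), int(seed) & 0x7FFFFFFF,
    )
    term_half2 = terminations - term_half1
    t_half = t_measure / 2.0
    f1, f2 = term_half1 / t_half, term_half2 / t_half
    se = math.sqrt(max(term_half1, 1) + max(term_half2, 1)) / t_half
    converged = abs(f1 - f2) <= 3.0 * se
    if not converged:
        warnings.warn(
            f"{profile.gene_id}: split-half flux estimates differ by more "
            f"than 3 SE ({f1:.4g} vs {f2:.4g}); increase t_measure",
            stacklevel=2,
        )
    return SimulationResult(
        gene_id=profile.gene_id,
        translation_rate=terminations / t_measure,
        density=density,
        terminations=int(terminations),
        initiations=int(initiations),
        collisions=float(blocked),
        elapsed_model_time=float(t_measure),
        flux_se=se / math.sqrt(2.0),
        converged=bool(converged),
    )


def transim_translation_rate(result: SimulationResult) -> float:
    """Steady-state protein flux: terminations per measured second."""
    if result.elapsed_model_time <= 0:
        raise ValueError("measurement window must be positive")
    return result.terminations / result.elapsed_model_time


# --- exact master-equation oracle ------------------------------------------


def _enumerate_states(L: int, ell: int) -> list[tuple[int, ...]]:
    """All admissible leading-edge configurations for an L-site lattice."""
    max_edge = L + ell - 1
    states: list[tuple[int, ...]] = []

    def extend(state: tuple[int, ...], min_next: int) -> None:
        states.append(state)
        for e in range(min_next, max_edge + 1):
            extend(state + (e,), e + ell)

    extend((), ell)
    return states


def exact_steady_state(
    profile: RateProfile, max_states: int = 20000
) -> dict[str, object]:
    """Exact stationary current and densities by solving the master equation.

    Enumerates every admissible ribosome configuration (feasible only for
    short lattices, L <= ~10 with footprint 1-2), builds the continuous-time
    generator with exactly the same transition rules as the simulator, and
    solves for the stationary distribution.  Returns the exact flux, the
    per-site densities, and the initiation flux (equal to the termination
    flux at stationarity).
    """
    k = np.asarray(profile.hop_rates, dtype=float)
    L = len(k)
    ell = profile.footprint
    states = _enumerate_states(L, ell)
    n = len(states)
    if n > max_states:
        raise ValueError(f"state space too large: {n} > {max_states}")
    index = {s: i for i, s in enumerate(states)}
    max_edge = L + ell - 1

    Q = np.zeros((n, n))
    for s, i in index.items():
        # initiation
        if not s or s[0] >= 2 * ell:
            target = tuple(sorted(s + (ell,)))
            Q[i, index[target]] += profile.alpha
        for j, p in enumerate(s):
            if p == max_edge:
                target = s[:j]  # p is necessarily the last element
                Q[i, index[target]] += profile.beta
            elif j == len(s) - 1 or s[j + 1] - p > ell:
                a = min(max(p - ell, 0), L - 1)
                target = s[:j] + (p + 1,) + s[j + 1:]
                Q[i, index[target]] += k[a]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))

    # stationary distribution: pi Q = 0, sum(pi) = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    current = sum(
        pi[i] * profile.beta for s, i in index.items() if s and s[-1] == max_edge
    )
    init_flux = sum(
        pi[i] * profile.alpha
        for s, i in index.items()
        if not s or s[0] >= 2 * ell
    )
    density = np.zeros(L)
    for s, i in index.items():
        for p in s:
            lo = max(p - ell + 1, 1)
            hi = min(p, L)
            density[lo - 1:hi] += pi[i]
    return {
        "current": float(current),
        "initiation_flux": float(init_flux),
        "density": density,
        "n_states": n,
    }


# --- per-gene orchestration ------------------------------------------------


def compute_rate_profiles(
    records: Sequence[GeneRecord],
    params: InitiationParams | None = None,
    dwell_table: Mapping[str, float] | None = None,
    beta: float = 10.0,
    footprint: int = 10,
    simulate: bool = False,
    seed: int = 0,
    t_burn: float | None = None,
    t_measure: float | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Initiation/elongation rates (and optionally TASEP rates) per gene.

    Returns a gene-indexed DataFrame with columns ``initiation_rate`` and
    ``elongation_rate`` (plus ``translation_rate``, ``mean_density`` and
    ``collisions`` when ``simulate``), and the list of genes discarded
    because their RBS was too short for the initiation model.  Each gene's
    simulation seed is derived deterministically from ``seed``.
    """
    params = params or InitiationParams()
    if dwell_table is None:
        dwell_table = default_dwell_times()
    rows = {}
    discarded: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        try:
            alpha = initiation_rate(rec.utr5, rec.cds, params)
        except RbsTooShortError:
            discarded.append((rec.gene_id, RBS_TOO_SHORT))
            continue
        hop, gene_rate = elongation_rates(rec.cds, dwell_table)
        row = {"initiation_rate": alpha, "elongation_rate": gene_rate}
        if simulate:
            profile = RateProfile(
                gene_id=rec.gene_id, alpha=alpha, hop_rates=hop,
                beta=beta, footprint=footprint,
            )
            res = tasep_simulate(
                profile, t_burn=t_burn, t_measure=t_measure,
                seed=(seed * 1000003 + i) & 0x7FFFFFFF,
            )
            row["translation_rate"] = res.translation_rate
            row["mean_density"] = float(res.density.mean())
            row["collisions"] = res.collisions
        rows[rec.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index"), discarded


# --- the simulator's exchange format ---------------------------------------


def write_transim_input(
    records: Iterable[GeneRecord], path: str | Path
) -> None:
    """Write (name, UTR+CDS sequence, 1-based start-site position) TSV."""
    with open(path, "w") as fh:
        fh.write("name\tsequence\tstart\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.utr5}{rec.cds}\t{len(rec.utr5) + 1}\n")


def read_transim_input(path: str | Path) -> list[tuple[str, str, str]]:
    """Read the (name, sequence, start) dialect back into (id, utr5, cds)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "sequence", "start"]:
            raise ValueError("expected header: name\\tsequence\\tstart")
        for line in fh:
            if not line.strip():
                continue
            name, seq, start = line.rstrip("\n").split("\t")[:3]
            s = int(start)
            if not 1 <= s <= len(seq):
                raise ValueError(f"{name}: start {s} outside sequence")
            out.append((name, seq[: s - 1].upper(), seq[s - 1:].upper()))
    return out
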