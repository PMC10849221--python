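"""RNA secondary-structure energy around the start codon.

Two interchangeable backends compute a minimum free energy (MFE, kcal/mol,
<= 0) for a sequence window:

* ``"nussinov"`` (default): base-pair maximization by the Nussinov dynamic
  program with a minimum hairpin loop of 3 unpaired bases and a pseudo-energy
  of -1.0 kcal/mol per pair.  Deterministic and dependency-free; used by the
  test suite.
* ``"vienna"``: nearest-neighbour thermodynamic MFE via the ViennaRNA python
  bindings, when importable.

Windows use the package coordinate convention (+1 = first base of the start
codon, no position 0, endpoints inclusive).  A window not fully covered by
the available sequence yields ``None`` (missing); dataset-level handling of
missingness lives in :mod:`ribopred.features`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mfe", "folding_energy_window", "window_sequence"]

_PAIR_ENERGY = -1.0
_MIN_LOOP = 3

# Watson-Crick + GU wobble, encoded A=0 C=1 G=2 T/U=3; 4 = ambiguity code,
# which never pairs under the fallback model.
_CAN_PAIR = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CAN_PAIR[_a, _b] = True

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


@njit(cache=False)
def _nussinov_pairs(seq: np.ndarray, can_pair: np.ndarray, min_loop: int) -> int:
    """Maximum number of nested base pairs (Nussinov DP)."""
    n = seq.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair[seq[i], seq[k]]:
                    left = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    val = 1 + left + right
                    if val > best:
                        best = val
            dp[i, j] = best
    return dp[0, n - 1] if n > 1 else 0


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 4) for c in seq.upper()], dtype=np.int64)


def mfe(seq: str, backend: str = "nussinov") -> float:
    """Folding energy (kcal/mol) of ``seq`` under the selected backend."""
    if len(seq) < 2:
        return 0.0
    if backend == "nussinov":
        pairs = _nussinov_pairs(_encode(seq), _CAN_PAIR, _MIN_LOOP)
        return _PAIR_ENERGY * pairs
    if backend == "vienna":
        import RNA

        _, energy = RNA.fold(seq.replace("T", "U"))
        return float(energy)
    raise ValueError(f"unknown folding backend {backend!r}")


def window_sequence(utr5: str, cds: str, window: tuple[int, int]) -> str | None:
    """Extract the subsequence for an inclusive coordinate window.

    Returns ``None`` when the available UTR/CDS does not cover the whole
    window.  Position -k is the k-th base upstream of the start codon;
    position +k the k-th base of the CDS.
    """
    start, end = window
    if start == 0 or end == 0:
        raise ValueError("coordinate 0 does not exist in this convention")
    if start > end:
        raise ValueError(f"invalid window {window}: start > end")
    out = []
    for pos in range(start, end + 1):
        if pos == 0:
            continue
        if pos < 0:
            idx = len(utr5) + pos
            if idx < 0:
                return None
            out.append(utr5[idx])
        else:
            idx = pos - 1
            if idx >= len(cds):
                return None
            out.append(cds[idx])
    return "".join(out)


def folding_energy_window(
    utr5: str,
    cds: str,
    window: tuple[int, int],
    backend: str = "nussinov",
) -> float | None:
    """MFE of a start-codon-anchored window, or None if not fully covered."""
    seq = window_sequence(utr5, cds, window)
    if seq is None:
        return None
    return mfe(seq, backend=backend)
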