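"""Codon substitution machinery shared by the simulator and the selection tests.

The model is a GY94-style Markov process on the 61 sense codons of the
universal genetic code (stop codons are excluded from the state space).
Instantaneous rates between codons differing at a single nucleotide are

    q_ij = pi_j * kappa^{I[transition]} * omega^{I[nonsynonymous]}

with kappa the transition/transversion rate ratio, omega = dN/dS, and pi the
stationary codon frequencies. Multi-nucleotide changes have rate zero.

Matrices here are *unscaled*; callers normalise so that branch lengths are in
expected substitutions per codon averaged over the site-class mixture (see
:func:`mixture_scale`). Because the process is time-reversible, transition
probabilities are computed through a symmetric eigendecomposition, which makes
repeated P(t) evaluations cheap.
"""

from __future__ import annotations

import numpy as np

NUCS = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")

# Universal genetic code, indexed by codon string.
_CODON_TABLE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_i = 0
for _n1 in NUCS:
    for _n2 in NUCS:
        for _n3 in NUCS:
            _CODON_TABLE[_n1 + _n2 + _n3] = _AA[_i]
            _i += 1

#: the 61 sense codons, in TCAG order (PAML's conventional ordering)
CODONS = tuple(c for c in _CODON_TABLE if _CODON_TABLE[c] != "*")
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61
AMINO_ACIDS = tuple(_CODON_TABLE[c] for c in CODONS)

GENETIC_CODE = dict(_CODON_TABLE)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def _build_masks():
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _build_masks()


def uniform_codon_freqs() -> np.ndarray:
    """Equal frequencies over the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_codon_freqs(position_freqs: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from a (3, 4) array of per-position nucleotide
    frequencies (columns in TCAG order), renormalised over sense codons."""
    position_freqs = np.asarray(position_freqs, dtype=float)
    if position_freqs.shape != (3, 4):
        raise ValueError("position_freqs must be (3, 4) in TCAG order")
    out = np.empty(N_CODONS)
    for i, codon in enumerate(CODONS):
        p = 1.0
        for k in range(3):
            p *= position_freqs[k, NUCS.index(codon[k])]
        out[i] = p
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies")
    return out / total


def empirical_f3x4(codon_columns: np.ndarray) -> np.ndarray:
    """F3x4 frequencies estimated from an integer codon-state matrix
    (rows = sequences, columns = sites; -1 = gap/missing)."""
    counts = np.zeros((3, 4))
    states = codon_columns[codon_columns >= 0]
    for s in np.unique(states):
        codon = CODONS[int(s)]
        n = np.count_nonzero(states == s)
        for k in range(3):
            counts[k, NUCS.index(codon[k])] += n
    counts += 0.1  # pseudocount keeps every codon reachable
    return f3x4_codon_freqs(counts / counts.sum(axis=1, keepdims=True))


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 rate matrix for one omega class."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("pi must be a 61-vector of frequencies summing to 1")
    Q = np.where(_SINGLE, 1.0, 0.0)
    Q = Q * np.where(_TRANSITION, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    Q = Q * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per unit time at stationarity: -sum_i pi_i q_ii."""
    return float(-np.dot(pi, np.diag(Q)))


def mixture_scale(kappa: float, omegas, proportions, pi: np.ndarray) -> float:
    """Scale factor making the *mixture* mean rate equal 1.

    ``omegas`` and ``proportions`` describe the site-class mixture (on
    background branches for branch-site models); dividing every Q by the
    returned value puts branch lengths in expected substitutions per codon.
    """
    omegas = np.asarray(omegas, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    r = sum(p * mean_rate(rate_matrix(kappa, w, pi), pi)
            for w, p in zip(omegas, proportions))
    if r <= 0:
        raise ValueError("mixture rate is zero; cannot scale")
    return float(r)


class ReversibleCodonMatrix:
    """Eigendecomposed reversible codon rate matrix with fast P(t).

    Uses the similarity transform B = D^{1/2} Q D^{-1/2} (D = diag(pi)),
    which is symmetric for reversible Q, so eigh applies.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.pi = np.asarray(pi, dtype=float)
        sqrt_pi = np.sqrt(self.pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)  # symmetrise roundoff
        self._eigval, U = np.linalg.eigh(B)
        self._left = U / sqrt_pi[:, None]        # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T   # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def codon_states(seq: str) -> np.ndarray:
    """Encode an in-frame DNA string as sense-codon state indices (-1 for any
    codon containing a gap or ambiguity)."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in CODON_INDEX:
            out[i // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at codon position {i // 3}")
        else:
            out[i // 3] = -1
    return out


def states_to_seq(states: np.ndarray) -> str:
    return "".join(CODONS[int(s)] if s >= 0 else "---" for s in states)


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon.upper().replace("U", "T")]
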