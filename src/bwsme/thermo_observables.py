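"""Free-energy profiles, landscapes, residue stabilities and intermediates.

The reaction coordinate (RC) is the number of structured blocks; grouping
microstates by RC gives the 1D free-energy profile dG_b = -RT ln(Z_b / Z).
Splitting the chain into N- and C-terminal halves and binning on the two
partial block counts gives the 2D landscape. Residue folding probabilities
p_i (constant within a block) yield per-residue stabilities through the logit
transform dG_s,i = -RT ln(p_i / (1 - p_i)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .ensemble_core import StateEnsemble

logger = logging.getLogger(__name__)


@dataclass
class FreeEnergyProfile1D:
    rc_blocks: np.ndarray       # 0..Nb
    dG: np.ndarray              # J/mol; +inf for empty bins
    T: float
    R: float = 8.314

    @property
    def rc_fraction(self) -> np.ndarray:
        return self.rc_blocks / self.rc_blocks[-1]

    @property
    def RT(self) -> float:
        return self.R * self.T

    def to_tsv(self) -> str:
        lines = ["rc_blocks\trc_fraction\tdG_kJ_mol"]
        for b, f, g in zip(self.rc_blocks, self.rc_fraction, self.dG):
            g_kj = "inf" if not np.isfinite(g) else f"{g / 1000.0:.6g}"
            lines.append(f"{b}\t{f:.6g}\t{g_kj}")
        return "\n".join(lines) + "\n"


@dataclass
class FreeEnergyLandscape2D:
    grid: np.ndarray            # (split+1, Nb-split+1) J/mol, +inf empty
    split_block: int            # 1-based: N-half is blocks 1..split_block
    T: float
    R: float = 8.314

    def to_tsv(self) -> str:
        lines = ["n_blocks_N\tn_blocks_C\tdG_kJ_mol"]
        for i in range(self.grid.shape[0]):
            for j in range(self.grid.shape[1]):
                g = self.grid[i, j]
                g_kj = "inf" if not np.isfinite(g) else f"{g / 1000.0:.6g}"
                lines.append(f"{i}\t{j}\t{g_kj}")
        return "\n".join(lines) + "\n"


@dataclass
class ResidueProbabilities:
    p: np.ndarray               # per residue, in [0, 1]
    T: float
    R: float = 8.314

    def __len__(self) -> int:
        return self.p.size


def _bin_log_weights(ensemble: StateEnsemble, counts: np.ndarray,
                     n_bins: int) -> np.ndarray:
    """logsumexp of state log-weights per integer bin value."""
    lw = ensemble.log_weights
    out = np.full(n_bins, -np.inf)
    order = np.argsort(counts, kind="stable")
    sorted_counts = counts[order]
    edges = np.searchsorted(sorted_counts, np.arange(n_bins + 1))
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if hi > lo:
            out[b] = logsumexp(lw[order[lo:hi]])
    return out


def free_energy_profile_1d(ensemble: StateEnsemble) -> FreeEnergyProfile1D:
    """1D profile over the number of structured blocks."""
    Nb = ensemble.Nb
    lse = _bin_log_weights(ensemble, ensemble.n_folded_blocks, Nb + 1)
    dG = -ensemble.RT * (lse - ensemble.log_Z)
    return FreeEnergyProfile1D(rc_blocks=np.arange(Nb + 1), dG=dG,
                               T=ensemble.T, R=ensemble.params.R)


def _half_counts(ensemble: StateEnsemble, split_block: int) -> tuple:
    """Folded-block counts in blocks [1..split] and [split+1..Nb] per state."""
    isl = ensemble.islands
    nN = np.zeros(ensemble.n_states, dtype=np.int64)
    nC = np.zeros(ensemble.n_states, dtype=np.int64)
    for col in (0, 2):
        has = isl[:, col] >= 0
        p = isl[has, col]
        q = isl[has, col + 1]
        nN[has] += np.clip(np.minimum(q, split_block - 1) - p + 1, 0, None)
        nC[has] += np.clip(q - np.maximum(p, split_block) + 1, 0, None)
    return nN, nC


def free_energy_landscape_2d(ensemble: StateEnsemble,
                             split_block: int) -> FreeEnergyLandscape2D:
    """2D landscape binned on (folded blocks in N-half, folded blocks in C-half).

    ``split_block`` is 1-based: the N-half comprises blocks 1..split_block.
    """
    Nb = ensemble.Nb
    if not 1 <= split_block < Nb:
        raise ValueError(f"split_block must be in [1, {Nb - 1}], got {split_block}")
    nN, nC = _half_counts(ensemble, split_block)
    n_rows = split_block + 1
    n_cols = Nb - split_block + 1
    flat = nN * n_cols + nC
    lse = _bin_log_weights(ensemble, flat, n_rows * n_cols)
    grid = (-ensemble.RT * (lse - ensemble.log_Z)).reshape(n_rows, n_cols)
    return FreeEnergyLandscape2D(grid=grid, split_block=split_block,
                                 T=ensemble.T, R=ensemble.params.R)


def residue_fold_probabilities(ensemble: StateEnsemble) -> ResidueProbabilities:
    """p_i = sum of normalized weights of states in which residue i is folded."""
    p_block = ensemble.block_fold_probabilities()
    p_res = p_block[ensemble.partition.residue_to_block]
    return ResidueProbabilities(p=p_res, T=ensemble.T, R=ensemble.params.R)


def _safe_logit(p: np.ndarray, RT: float) -> np.ndarray:
    eps = 1e-12
    if np.any(p < eps) or np.any(p > 1 - eps):
        warnings.warn("folding probabilities clipped to (1e-12, 1-1e-12) "
                      "before the logit transform")
    pc = np.clip(p, eps, 1.0 - eps)
    return -RT * np.log(pc / (1.0 - pc))


def residue_stability(p: ResidueProbabilities) -> np.ndarray:
    """Per-residue stability dG_s,i = -RT ln(p_i/(1-p_i)); negative = stable."""
    return _safe_logit(np.asarray(p.p, dtype=float), p.R * p.T)


def element_stability(p: ResidueProbabilities, element: Sequence[int]) -> float:
    """Mean stability of a structural element: logit of the MEAN probability.

    ``element`` is an iterable of 1-based residue indices. The probabilities
    are averaged first and the logit applied once (not a mean of per-residue
    stabilities).
    """
    idx = np.asarray(list(element), dtype=int)
    if idx.size == 0:
        raise ValueError("element range is empty")
    mean_p = float(np.mean(p.p[idx - 1]))
    return float(_safe_logit(np.array([mean_p]), p.R * p.T)[0])


def count_intermediates(profile: FreeEnergyProfile1D,
                        threshold_RT: float = 1.0) -> int:
    """Number of partially structured intermediates on a 1D profile.

    A strict local minimum counts as an intermediate when it is separated
    from its surviving neighbors on both sides by barriers of at least
    ``threshold_RT * RT``; the lowest-RC and highest-RC basins are the
    unfolded/folded states and never counted. Minima failing the test are
    merged into the deeper adjacent basin, smallest separating barrier first,
    until all survivors pass.
    """
    dG = np.asarray(profile.dG, dtype=float)
    finite_idx = np.flatnonzero(np.isfinite(dG))
    if finite_idx.size == 0:
        raise ValueError("profile has no finite bins")
    g = dG[finite_idx]
    n = g.size
    if n < 3:
        return 0

    minima = [k for k in range(n)
              if (k == 0 or g[k] < g[k - 1]) and (k == n - 1 or g[k] < g[k + 1])]
    # treat profile endpoints as basin anchors even if not strict minima
    if not minima or minima[0] != 0:
        if g[0] <= g[1]:
            minima.insert(0, 0)
    if minima[-1] != n - 1 and g[n - 1] <= g[n - 2]:
        minima.append(n - 1)
    if len(minima) <= 2:
        return 0

    thr = threshold_RT * profile.RT

    def barrier(a: int, b: int) -> float:
        return float(np.max(g[a:b + 1]))

    while True:
        if len(minima) <= 2:
            return 0
        worst_k = None
        worst_sep = np.inf
        for pos in range(1, len(minima) - 1):
            m = minima[pos]
            left = barrier(minima[pos - 1], m) - g[m]
            right = barrier(m, minima[pos + 1]) - g[m]
            sep = min(left, right)
            if sep < worst_sep - 1e-12 or (abs(sep - worst_sep) <= 1e-12
                                           and worst_k is not None
                                           and g[m] > g[minima[worst_k]]):
                worst_sep, worst_k = sep, pos
        if worst_sep >= thr:
            return len(minima) - 2
        del minima[worst_k]


def half_fold_probabilities_at_rc(ensemble: StateEnsemble, rc_fraction: float,
                                  n_half: Sequence[int]) -> tuple:
    """Mean conditional folding probability of the N- and C-half residue sets.

    Conditions on the states in the RC bin nearest ``rc_fraction * Nb``
    (nearest non-empty bin, logged) and averages the conditional per-residue
    folding probabilities over ``n_half`` (1-based residue indices) and its
    complement.
    """
    if ensemble.n_states == 0:
        raise ValueError("empty ensemble")
    Nb = ensemble.Nb
    nfold = ensemble.n_folded_blocks
    target = int(round(rc_fraction * Nb))
    occupied = np.unique(nfold)
    if target not in occupied:
        nearest = int(occupied[np.argmin(np.abs(occupied - target))])
        logger.info("RC bin %d empty; using nearest non-empty bin %d", target, nearest)
        target = nearest
    mask = nfold == target
    p_block = ensemble.block_fold_probabilities(state_mask=mask)
    p_res = p_block[ensemble.partition.residue_to_block]
    n_res = ensemble.partition.n_residues
    n_idx = np.asarray(list(n_half), dtype=int)
    c_idx = np.setdiff1d(np.arange(1, n_res + 1), n_idx)
    return float(np.mean(p_res[n_idx - 1])), float(np.mean(p_res[c_idx - 1]))


def default_half_split(ensemble: StateEnsemble) -> tuple:
    """(N-half residue indices, split_block) at the residue midpoint."""
    part = ensemble.partition
    mid_res = part.n_residues // 2
    split_block = part.block_of(mid_res) + 1  # 1-based block index
    split_block = min(max(split_block, 1), part.Nb - 1)
    last_res = part.blocks[split_block - 1][1]
    return list(range(1, last_res + 1)), split_block


def residue_table_tsv(p: ResidueProbabilities) -> str:
    dg = residue_stability(p)
    lines = ["residue\tp_fold\tdG_s_kJ_mol"]
    for i, (pi, g) in enumerate(zip(p.p, dg), start=1):
        lines.append(f"{i}\t{pi:.6g}\t{g / 1000.0:.6g}")
    return "\n".join(lines) + "\n"
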