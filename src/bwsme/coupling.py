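"""Pairwise thermodynamic coupling free energies between residues.

For every residue pair (i, j) the ensemble is split into four sub-ensembles
by the folded status of the two residues; their normalized probability sums
(p_ff, p_fu, p_uf, p_uu, totalling 1) define

    dG_+ = RT ln(p_ff / p_uf),   dG_- = RT ln(p_fu / p_uu),
    dG_c = dG_+ - dG_-

dG_c is symmetric in (i, j) by construction. Residues sharing a block are
perfectly correlated within the block approximation and are reported as
missing (NaN), as is the diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_core import BlockPartition, StateEnsemble

logger = logging.getLogger(__name__)

_FLOOR = 1e-300


@dataclass
class CouplingMatrices:
    """N x N coupling free-energy matrices (J/mol), NaN where undefined."""

    dG_plus: np.ndarray
    dG_minus: np.ndarray
    dG_c: np.ndarray
    p_ff: np.ndarray
    p_fu: np.ndarray
    p_uf: np.ndarray
    p_uu: np.ndarray
    T: float

    @property
    def n_residues(self) -> int:
        return self.dG_c.shape[0]

    def to_tsv(self) -> str:
        lines = ["i\tj\tdG_plus_kJ\tdG_minus_kJ\tdG_c_kJ"]
        n = self.n_residues
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                vals = (self.dG_plus[i, j], self.dG_minus[i, j], self.dG_c[i, j])
                txt = "\t".join("nan" if not np.isfinite(v) else f"{v / 1000.0:.6g}"
                                for v in vals)
                lines.append(f"{i + 1}\t{j + 1}\t{txt}")
        return "\n".join(lines) + "\n"


@dataclass
class CouplingSummary:
    mean_dGc: np.ndarray        # per-residue row average, J/mol
    z: np.ndarray               # per-protein Z-score
    strong_mask: np.ndarray     # z > 1
    f_c: float                  # fraction strongly coupled

    def to_tsv(self) -> str:
        lines = ["residue\tmean_dGc_kJ\tz\tstrong"]
        for i, (m, z, s) in enumerate(zip(self.mean_dGc, self.z, self.strong_mask),
                                      start=1):
            lines.append(f"{i}\t{m / 1000.0:.6g}\t{z:.6g}\t{int(s)}")
        return "\n".join(lines) + "\n"


def coupling_free_energies(ensemble: StateEnsemble,
                           partition: BlockPartition = None) -> CouplingMatrices:
    """Coupling free-energy matrices from the four sub-ensemble sums.

    The per-pair sums are computed at block level (residue folded status is a
    block property) and expanded to residue resolution. Zero-probability
    sub-ensembles are floored at 1e-300 with a warning. An ensemble that is
    degenerately all-folded or all-unfolded has empty sub-ensembles and is an
    error.
    """
    part = partition if partition is not None else ensemble.partition
    res_block = part.residue_to_block
    RT = ensemble.RT

    p_f = ensemble.block_fold_probabilities()
    if np.all(p_f > 1.0 - 1e-12) or np.all(p_f < 1e-12):
        raise ValueError("degenerate ensemble: all blocks (un)folded; "
                         "sub-ensembles are empty")
    pff_b, pfu_b, puu_b = ensemble.joint_block_probabilities()

    a = res_block[:, None]
    b = res_block[None, :]
    pff = pff_b[a, b]
    pfu = pfu_b[a, b]
    puf = pfu_b[b, a]
    puu = puu_b[a, b]

    same_block = a == b
    floored = False
    mats = []
    for m in (pff, pfu, puf, puu):
        if np.any(m[~same_block] < _FLOOR):
            floored = True
        mats.append(np.where(m < _FLOOR, _FLOOR, m))
    pff, pfu, puf, puu = mats
    if floored:
        warnings.warn("some sub-ensemble probability sums were floored at 1e-300")

    with np.errstate(divide="ignore", invalid="ignore"):
        dg_plus = RT * np.log(pff / puf)
        dg_minus = RT * np.log(pfu / puu)
    dg_c = dg_plus - dg_minus
    for m in (dg_plus, dg_minus, dg_c, pff, pfu, puf, puu):
        m[same_block] = np.nan
    return CouplingMatrices(dG_plus=dg_plus, dG_minus=dg_minus, dG_c=dg_c,
                            p_ff=pff, p_fu=pfu, p_uf=puf, p_uu=puu,
                            T=ensemble.T)


def mean_coupling(matrices: CouplingMatrices) -> CouplingSummary:
    """Per-residue mean dG_c, per-protein Z-scores and the strongly coupled
    fraction f_c (Z > 1)."""
    n = matrices.n_residues
    if n < 3:
        raise ValueError("need at least 3 residues")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(matrices.dG_c, axis=1)
    sd = np.nanstd(mean)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("zero variance in mean coupling; all Z-scores set to 0")
        z = np.zeros(n)
    else:
        z = (mean - np.nanmean(mean)) / sd
    strong = z > 1.0
    return CouplingSummary(mean_dGc=mean, z=z, strong_mask=strong,
                           f_c=float(np.mean(strong)))


def inter_element_coupling(matrices: CouplingMatrices,
                           elements: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Mean dG_c between named residue ranges (e.g. TM1..TM7).

    Entry (a, b) is the mean over residue pairs (i in a, j in b); the diagonal
    is the within-element mean (same-block pairs are already missing).
    Elements must not overlap.
    """
    names = list(elements)
    idx = {}
    for name in names:
        members = np.asarray(list(elements[name]), dtype=int)
        if members.size == 0:
            raise ValueError(f"element {name!r} is empty")
        idx[name] = members - 1
    all_members = np.concatenate(list(idx.values()))
    if np.unique(all_members).size != all_members.size:
        raise ValueError("elements overlap")

    out = np.empty((len(names), len(names)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x, na in enumerate(names):
            for y, nb in enumerate(names):
                sub = matrices.dG_c[np.ix_(idx[na], idx[nb])]
                out[x, y] = np.nanmean(sub)
    return pd.DataFrame(out, index=names, columns=names)


def differential_coupling(active, inactive):
    """Elementwise active-minus-inactive difference; NaNs propagate.

    Accepts two :class:`CouplingMatrices` (residue level) or two DataFrames /
    arrays of identical shape (element level).
    """
    if isinstance(active, CouplingMatrices) and isinstance(inactive, CouplingMatrices):
        if active.dG_c.shape != inactive.dG_c.shape:
            raise ValueError("residue dimensions differ between active and inactive")
        return active.dG_c - inactive.dG_c
    a = active.values if isinstance(active, pd.DataFrame) else np.asarray(active)
    b = inactive.values if isinstance(inactive, pd.DataFrame) else np.asarray(inactive)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between active and inactive matrices")
    diff = a - b
    if isinstance(active, pd.DataFrame):
        return pd.DataFrame(diff, index=active.index, columns=active.columns)
    return diff
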