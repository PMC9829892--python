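"""Block partitioning, microstate enumeration and the bWSME partition function.

Residues are grouped into blocks of (at most) ``block_size`` consecutive
residues, never spanning two secondary-structure elements. A microstate is a
binary folded/unfolded assignment over blocks with at most two folded islands:

* ``U``     -- the fully unfolded reference state (free energy 0, weight 1);
* ``SSA``   -- a single island of folded blocks;
* ``DSA``   -- two islands that do not interact with each other;
* ``DSAwL`` -- the same two islands with their native inter-island contacts
  active, at the additional entropic cost of fixing every residue of the
  intervening loop.

The free energy of a microstate is

    dG = dG_stab - T * dS_conf

where ``dG_stab`` sums, over active residue pairs, the van der Waals term
``n_ij * xi``, the contact-scaled solvation term
``n_ij * dCp_cont * ((T - T_ref) - T ln(T/T_ref))`` and the Debye-Hueckel
charge-charge energy, and ``dS_conf`` sums per-residue conformational
entropies over the residues fixed by the state. The partition function is
``Z = sum_i exp(-dG_i / RT)`` with the unfolded state contributing 1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import constants as sc
from scipy.special import logsumexp

from .errors import CalibrationError, StructureError
from .parameters import ModelParameters
from .structure_io import ChargeSet, ContactMap, ProteinStructure, SS_COIL

logger = logging.getLogger(__name__)

#: N_A e^2 / (4 pi eps0) in J * Angstrom / mol -- Coulomb prefactor so that
#: E = COULOMB_JA * q_i q_j * exp(-kappa r) / (dielectric * r) with r in A.
COULOMB_JA = sc.Avogadro * sc.e ** 2 / (4.0 * math.pi * sc.epsilon_0) * 1e10


def debye_kappa(T: float, ionic_strength: float, dielectric: float) -> float:
    """Inverse Debye screening length in 1/Angstrom."""
    if ionic_strength <= 0:
        return 0.0
    # 2 * N_A * e^2 * (1000 * I) / (eps0 * eps_r * kB * T), converted to 1/A
    kappa_sq = (2.0 * sc.Avogadro * sc.e ** 2 * 1000.0 * ionic_strength
                / (sc.epsilon_0 * dielectric * sc.Boltzmann * T))
    return math.sqrt(kappa_sq) * 1e-10


def solvation_g(T: float, T_ref: float) -> float:
    """Temperature factor of the per-contact solvation free energy."""
    return (T - T_ref) - T * math.log(T / T_ref)


# ---------------------------------------------------------------------------
# Block partition


@dataclass(frozen=True)
class BlockPartition:
    """Contiguous residue blocks covering 1..N, none spanning two SS elements."""

    blocks: tuple                 # tuple[(start, end)] 1-based inclusive
    residue_names: tuple          # 3-letter codes, 1..N
    ss_labels: tuple              # helix/strand/coil, 1..N
    block_size: int

    @property
    def Nb(self) -> int:
        return len(self.blocks)

    @property
    def n_residues(self) -> int:
        return self.blocks[-1][1]

    @property
    def residue_to_block(self) -> np.ndarray:
        """0-based block index for each residue (array position = residue - 1)."""
        out = np.empty(self.n_residues, dtype=np.int32)
        for b, (s, e) in enumerate(self.blocks):
            out[s - 1:e] = b
        return out

    def block_of(self, residue_index: int) -> int:
        return int(self.residue_to_block[residue_index - 1])


def partition_into_blocks(structure: ProteinStructure, block_size: int) -> BlockPartition:
    """Chunk the chain into folding blocks of at most ``block_size`` residues.

    The sequence is first cut at every secondary-structure-element boundary
    (maximal runs of one label); each segment is then chunked left to right,
    with a shorter trailing block allowed.
    """
    n = len(structure)
    if n == 0:
        raise StructureError("empty structure")
    labels = structure.ss_labels
    if any(l is None for l in labels):
        raise StructureError("structure has no secondary-structure labels; "
                             "run assign_secondary_structure first")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    blocks = []
    seg_start = 1
    for i in range(2, n + 2):
        if i == n + 1 or labels[i - 1] != labels[seg_start - 1]:
            s = seg_start
            while s <= i - 1:
                e = min(s + block_size - 1, i - 1)
                blocks.append((s, e))
                s = e + 1
            seg_start = i
    return BlockPartition(
        blocks=tuple(blocks),
        residue_names=tuple(structure.sequence),
        ss_labels=tuple(labels),
        block_size=block_size,
    )


def residue_entropies(partition: BlockPartition, params: ModelParameters) -> np.ndarray:
    """Per-residue conformational entropy of fixing (J/mol/K, negative)."""
    out = np.empty(partition.n_residues)
    for k, (name, ss) in enumerate(zip(partition.residue_names, partition.ss_labels)):
        if name == "PRO":
            out[k] = params.dS_pro
        else:
            out[k] = params.dS_res + (params.ddS_coil if ss == SS_COIL else 0.0)
    return out


# ---------------------------------------------------------------------------
# Microstates


@dataclass(frozen=True)
class Microstate:
    """Folded-island assignment over blocks (1-based inclusive block ranges)."""

    kind: str                  # U | SSA | DSA | DSAwL
    islands: tuple             # () | ((p,q),) | ((p1,q1),(p2,q2))

    def __post_init__(self):
        if self.kind == "U" and self.islands:
            raise ValueError("U state has no islands")
        if self.kind == "SSA" and len(self.islands) != 1:
            raise ValueError("SSA state has exactly one island")
        if self.kind in ("DSA", "DSAwL"):
            if len(self.islands) != 2:
                raise ValueError(f"{self.kind} state has exactly two islands")
            (p1, q1), (p2, q2) = self.islands
            if not (p1 <= q1 and p2 <= q2 and p2 >= q1 + 2):
                raise ValueError("islands must be ordered and separated by >= 1 block")
        for p, q in self.islands:
            if p > q:
                raise ValueError("island bounds out of order")

    @property
    def n_folded_blocks(self) -> int:
        return sum(q - p + 1 for p, q in self.islands)


def count_states(Nb: int) -> int:
    """Number of microstates: 1 (U) + C(Nb+1, 2) SSA + 2 C(Nb+1, 4) DSA/DSAwL."""
    if Nb < 1:
        raise ValueError("Nb must be >= 1")
    return 1 + math.comb(Nb + 1, 2) + 2 * math.comb(Nb + 1, 4)


_STATE_INDEX_CACHE: dict = {}


def _state_index(Nb: int):
    """Cached microstate index arrays for a given block count.

    Returns (ssa_p, ssa_q, p1, q1, p2, q2), all 0-based block indices; the
    four-tuples are lexicographically ordered and satisfy p2 >= q1 + 2.
    """
    cached = _STATE_INDEX_CACHE.get(Nb)
    if cached is not None:
        return cached
    ssa_p, ssa_q = np.triu_indices(Nb)
    ssa_p = ssa_p.astype(np.int32)
    ssa_q = ssa_q.astype(np.int32)
    n4 = math.comb(Nb + 1, 4)
    if n4:
        combo = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(Nb + 1), 4)),
            dtype=np.int32, count=4 * n4,
        ).reshape(n4, 4)
        p1, q1 = combo[:, 0], combo[:, 1] - 1
        p2, q2 = combo[:, 2], combo[:, 3] - 1
    else:
        p1 = q1 = p2 = q2 = np.empty(0, dtype=np.int32)
    result = (ssa_p, ssa_q, p1, q1, p2, q2)
    if Nb <= 512:  # keep the cache bounded
        _STATE_INDEX_CACHE[Nb] = result
    return result


def enumerate_states(partition) -> list:
    """All microstates in deterministic order.

    Order: U first, then SSA states lexicographic by (p, q), then each
    two-island configuration in lexicographic order -- DSA immediately
    followed by its DSAwL twin.
    """
    Nb = partition.Nb if isinstance(partition, BlockPartition) else int(partition)
    ssa_p, ssa_q, p1, q1, p2, q2 = _state_index(Nb)
    states = [Microstate("U", ())]
    for p, q in zip(ssa_p, ssa_q):
        states.append(Microstate("SSA", ((int(p) + 1, int(q) + 1),)))
    for a, b, c, d in zip(p1, q1, p2, q2):
        islands = ((int(a) + 1, int(b) + 1), (int(c) + 1, int(d) + 1))
        states.append(Microstate("DSA", islands))
        states.append(Microstate("DSAwL", islands))
    return states


# ---------------------------------------------------------------------------
# Energy evaluation


class BlockSystem:
    """Precomputed block-level interaction matrices for fast state evaluation.

    The interaction between two blocks a <= b at temperature T is

        W[a, b] = n_ab * (xi + dCp_cont * g(T)) + E_elec(a, b; T)

    where ``n_ab`` counts native heavy-atom contacts between residues of the
    two blocks. Island energies and inter-island cross terms are rectangle
    sums of W, evaluated for all islands at once through 2D prefix sums.
    """

    def __init__(self, partition: BlockPartition, contacts: ContactMap,
                 charges: ChargeSet, params: ModelParameters):
        self.partition = partition
        self.params = params
        Nb = partition.Nb
        self.Nb = Nb
        res_block = partition.residue_to_block

        # contact counts per block pair (symmetric, diagonal = intra-block)
        Cn = np.zeros((Nb, Nb))
        for (i, j), n in contacts.items():
            a, b = res_block[i - 1], res_block[j - 1]
            Cn[a, b] += n
            if a != b:
                Cn[b, a] += n
        self.Cn = Cn

        # charge pairs (between distinct charge entries)
        ents = charges.entries if charges is not None else ()
        qq, rr, ca, cb = [], [], [], []
        for x in range(len(ents)):
            for y in range(x + 1, len(ents)):
                e1, e2 = ents[x], ents[y]
                r = math.dist(e1.site_xyz, e2.site_xyz)
                if r == 0.0:
                    continue
                qq.append(e1.charge * e2.charge)
                rr.append(r)
                ca.append(res_block[e1.residue_index - 1])
                cb.append(res_block[e2.residue_index - 1])
        self._qq = np.array(qq)
        self._rr = np.array(rr)
        self._ca = np.array(ca, dtype=np.int32)
        self._cb = np.array(cb, dtype=np.int32)

        # per-block entropy and its prefix sums
        s_res = residue_entropies(partition, params)
        s_blk = np.array([s_res[s - 1:e].sum() for s, e in partition.blocks])
        self.S_pref = np.concatenate([[0.0], np.cumsum(s_blk)])

        self._index = _state_index(Nb)
        self._features_cache = None

    def _segment_entropy(self, a, b):
        """Entropy of fixing blocks a..b inclusive (0-based); empty if a > b."""
        return self.S_pref[np.maximum(b + 1, a)] - self.S_pref[a]

    def _per_state_sums(self, M: np.ndarray) -> np.ndarray:
        """Sum of M[a, b] over active unordered block pairs, per state.

        Active pairs are all pairs inside an island plus, for DSAwL states,
        all pairs spanning the two islands. Returned in canonical state
        order (U = 0, SSA, interleaved DSA/DSAwL).
        """
        Nb = self.Nb
        P = np.zeros((Nb + 1, Nb + 1))
        P[1:, 1:] = M.cumsum(0).cumsum(1)
        diag_pref = np.concatenate([[0.0], np.cumsum(np.diag(M))])
        ssa_p, ssa_q, p1, q1, p2, q2 = self._index

        def island(p, q):
            square = P[q + 1, q + 1] - P[p, q + 1] - P[q + 1, p] + P[p, p]
            return 0.5 * (square + diag_pref[q + 1] - diag_pref[p])

        n_ssa, n4 = ssa_p.size, p1.size
        out = np.empty(1 + n_ssa + 2 * n4)
        out[0] = 0.0
        out[1:1 + n_ssa] = island(ssa_p, ssa_q)
        if n4:
            two = island(p1, q1) + island(p2, q2)
            cross = (P[q1 + 1, q2 + 1] - P[p1, q2 + 1]
                     - P[q1 + 1, p2] + P[p1, p2])
            out[1 + n_ssa::2] = two
            out[2 + n_ssa::2] = two + cross
        return out

    def _per_state_entropy(self) -> np.ndarray:
        """Conformational entropy fixed by each state (DSAwL includes loop)."""
        ssa_p, ssa_q, p1, q1, p2, q2 = self._index
        n_ssa, n4 = ssa_p.size, p1.size
        out = np.empty(1 + n_ssa + 2 * n4)
        out[0] = 0.0
        out[1:1 + n_ssa] = self._segment_entropy(ssa_p, ssa_q)
        if n4:
            s_isl = self._segment_entropy(p1, q1) + self._segment_entropy(p2, q2)
            out[1 + n_ssa::2] = s_isl
            out[2 + n_ssa::2] = s_isl + self._segment_entropy(q1 + 1, p2 - 1)
        return out

    @property
    def _features(self) -> tuple:
        """T-independent per-state features (contacts, entropy, charge activity).

        The free energy of every state factorizes as

            dG_i(T) = Nc_i * (xi + dCp * g(T)) - T * S_i + sum_g A_ig * e_g(T)

        with Nc_i the active native-contact count, S_i the fixed entropy and
        A_ig a 0/1 activity flag for each distinct block pair carrying
        charge-charge interactions (energy e_g at temperature T).
        """
        if self._features_cache is None:
            nc = self._per_state_sums(self.Cn)
            s = self._per_state_entropy()
            groups = {}
            for k in range(self._qq.size):
                a, b = int(self._ca[k]), int(self._cb[k])
                groups.setdefault((min(a, b), max(a, b)), []).append(k)
            keys = sorted(groups)
            acts = []
            for a, b in keys:
                M = np.zeros((self.Nb, self.Nb))
                M[a, b] = M[b, a] = 1.0
                acts.append(self._per_state_sums(M))
            A = (np.stack(acts, axis=1) if acts
                 else np.empty((nc.size, 0)))
            members = [np.array(groups[k], dtype=np.int64) for k in keys]
            self._features_cache = (nc, s, A, members)
        return self._features_cache

    def _group_energies(self, T: float) -> np.ndarray:
        """Debye-Hueckel energy per charge block-pair group at T, J/mol."""
        p = self.params
        _, _, _, members = self._features
        kappa = debye_kappa(T, p.ionic_strength, p.dielectric)
        e_pair = (COULOMB_JA * self._qq * np.exp(-kappa * self._rr)
                  / (p.dielectric * self._rr))
        return np.array([e_pair[m].sum() for m in members])

    def all_free_energies(self, T: float, xi: Optional[float] = None) -> np.ndarray:
        """Per-state dG in canonical order (U, SSA, interleaved DSA/DSAwL)."""
        if T <= 0:
            raise ValueError("temperature must be positive")
        p = self.params
        xi = p.xi if xi is None else xi
        nc, s, A, _ = self._features
        dg = nc * (xi + p.dCp_cont * solvation_g(T, p.T_ref)) - T * s
        if A.shape[1]:
            dg += A @ self._group_energies(T)
        return dg

    def log_partition(self, T: float, xi: Optional[float] = None) -> float:
        lw = -self.all_free_energies(T, xi=xi) / (self.params.R * T)
        m = lw.max()
        return float(m + np.log(np.exp(lw - m).sum()))

    def log_partition_grid(self, T_grid: np.ndarray,
                           xi: Optional[float] = None) -> np.ndarray:
        """ln Z over a temperature grid, evaluated by chunked matrix algebra."""
        p = self.params
        xi = p.xi if xi is None else xi
        nc, s, A, _ = self._features
        T = np.asarray(T_grid, dtype=float)
        c1 = np.array([xi + p.dCp_cont * solvation_g(t, p.T_ref) for t in T])
        E = (np.stack([self._group_energies(t) for t in T], axis=1)
             if A.shape[1] else np.empty((0, T.size)))
        inv_rt = 1.0 / (p.R * T)
        run_max = np.full(T.size, -np.inf)
        run_sum = np.zeros(T.size)
        chunk = 65536
        for lo in range(0, nc.size, chunk):
            hi = min(lo + chunk, nc.size)
            dg = np.outer(nc[lo:hi], c1) - np.outer(s[lo:hi], T)
            if A.shape[1]:
                dg += A[lo:hi] @ E
            lw = -dg * inv_rt
            m = lw.max(axis=0)
            new_max = np.maximum(run_max, m)
            run_sum = (run_sum * np.exp(run_max - new_max)
                       + np.exp(lw - new_max).sum(axis=0))
            run_max = new_max
        return run_max + np.log(run_sum)


def state_free_energy(state: Microstate, partition: BlockPartition,
                      contacts: ContactMap, charges: Optional[ChargeSet],
                      params: ModelParameters, T: float) -> float:
    """Free energy of a single microstate (reference implementation, J/mol).

    Straightforward loops over contact and charge pairs; the vectorized
    engine in :class:`BlockSystem` is validated against this function and
    against the independent oracle in :mod:`bwsme.fixtures`.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if state.kind == "U":
        return 0.0
    res_block = partition.residue_to_block
    island_of = {}
    for isl_idx, (p, q) in enumerate(state.islands):
        for b in range(p - 1, q):
            island_of[b] = isl_idx

    def pair_active(i: int, j: int) -> bool:
        bi, bj = res_block[i - 1], res_block[j - 1]
        if bi not in island_of or bj not in island_of:
            return False
        if state.kind == "DSA" and island_of[bi] != island_of[bj]:
            return False
        return True

    p = params
    g = solvation_g(T, p.T_ref)
    e_stab = 0.0
    for (i, j), n in contacts.items():
        if pair_active(i, j):
            e_stab += n * (p.xi + p.dCp_cont * g)
    if charges is not None and len(charges) > 1:
        kappa = debye_kappa(T, p.ionic_strength, p.dielectric)
        ents = charges.entries
        for x in range(len(ents)):
            for y in range(x + 1, len(ents)):
                e1, e2 = ents[x], ents[y]
                r = math.dist(e1.site_xyz, e2.site_xyz)
                if r == 0.0 or not pair_active(e1.residue_index, e2.residue_index):
                    continue
                e_stab += (COULOMB_JA * e1.charge * e2.charge
                           * math.exp(-kappa * r) / (p.dielectric * r))

    s_res = residue_entropies(partition, params)
    fixed_blocks = set(island_of)
    if state.kind == "DSAwL":
        (p1, q1), (p2, q2) = state.islands
        fixed_blocks |= set(range(q1, p2 - 1))  # 0-based loop blocks
    s_conf = 0.0
    for b in fixed_blocks:
        s, e = partition.blocks[b]
        s_conf += s_res[s - 1:e].sum()
    return e_stab - T * s_conf


# ---------------------------------------------------------------------------
# StateEnsemble


@dataclass
class StateEnsemble:
    """The enumerated microstate ensemble at one temperature.

    Stores per-state free energies and island boundaries as flat arrays
    (O(states) scalars). ``states`` materializes :class:`Microstate` objects
    on demand.
    """

    partition: BlockPartition
    params: ModelParameters
    T: float
    free_energies: np.ndarray       # J/mol, canonical state order
    kinds: np.ndarray               # uint8: 0=U, 1=SSA, 2=DSA, 3=DSAwL
    islands: np.ndarray             # (n, 4) int32 [p1,q1,p2,q2] 0-based, -1 absent

    KIND_NAMES = ("U", "SSA", "DSA", "DSAwL")

    @property
    def n_states(self) -> int:
        return self.free_energies.size

    @property
    def Nb(self) -> int:
        return self.partition.Nb

    @property
    def RT(self) -> float:
        return self.params.R * self.T

    @property
    def log_weights(self) -> np.ndarray:
        return -self.free_energies / self.RT

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    @property
    def log_Z(self) -> float:
        return float(logsumexp(self.log_weights))

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_weights - self.log_Z)

    @property
    def n_folded_blocks(self) -> np.ndarray:
        isl = self.islands
        n1 = np.where(isl[:, 0] >= 0, isl[:, 1] - isl[:, 0] + 1, 0)
        n2 = np.where(isl[:, 2] >= 0, isl[:, 3] - isl[:, 2] + 1, 0)
        return (n1 + n2).astype(np.int32)

    @property
    def states(self) -> list:
        return enumerate_states(self.partition)

    # -- block-level folded statistics -----------------------------------

    def block_fold_probabilities(self, state_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """P(block folded), optionally conditioned on a subset of states."""
        lw = self.log_weights
        if state_mask is not None:
            lw = np.where(state_mask, lw, -np.inf)
        prob = np.exp(lw - logsumexp(lw))
        # direct masked sums per block: positive accumulation keeps full
        # relative accuracy even for blocks that almost never fold
        p1, q1, p2, q2 = (self.islands[:, k] for k in range(4))
        out = np.empty(self.Nb)
        for b in range(self.Nb):
            folded = ((p1 <= b) & (b <= q1)) | ((0 <= p2) & (p2 <= b) & (b <= q2))
            out[b] = prob[folded].sum()
        return out

    def joint_block_probabilities(self, chunk: int = 65536) -> tuple:
        """Directly accumulated sub-ensemble sums at block level.

        Returns (P_ff, P_fu, P_uu) with P_ff[a, b] = P(a folded, b folded),
        P_fu[a, b] = P(a folded, b unfolded), P_uu[a, b] = P(both unfolded);
        P_uf is the transpose of P_fu. Each sum is a direct accumulation of
        state probabilities (no subtractions), so small sums keep full
        relative accuracy.
        """
        prob = self.probabilities
        Nb = self.Nb
        isl = self.islands
        p_ff = np.zeros((Nb, Nb))
        p_fu = np.zeros((Nb, Nb))
        p_uu = np.zeros((Nb, Nb))
        for lo in range(0, self.n_states, chunk):
            hi = min(lo + chunk, self.n_states)
            diff = np.zeros((hi - lo, Nb + 1))
            rows = np.arange(hi - lo)
            for col in (0, 2):
                has = isl[lo:hi, col] >= 0
                diff[rows[has], isl[lo:hi, col][has]] += 1.0
                diff[rows[has], isl[lo:hi, col + 1][has] + 1] -= 1.0
            F = np.cumsum(diff[:, :-1], axis=1)
            U = 1.0 - F
            Fw = F * prob[lo:hi, None]
            Uw = U * prob[lo:hi, None]
            p_ff += Fw.T @ F
            p_fu += Fw.T @ U
            p_uu += Uw.T @ U
        return p_ff, p_fu, p_uu

    def joint_block_ff(self, chunk: int = 65536) -> np.ndarray:
        """P(block a folded AND block b folded) for all block pairs."""
        return self.joint_block_probabilities(chunk)[0]


def compute_partition_function(partition: BlockPartition, contacts: ContactMap,
                               charges: Optional[ChargeSet], params: ModelParameters,
                               T: float) -> StateEnsemble:
    """Enumerate and weight every microstate of the bWSME ensemble at T."""
    system = BlockSystem(partition, contacts, charges, params)
    dg = system.all_free_energies(T)
    Nb = partition.Nb
    ssa_p, ssa_q, p1, q1, p2, q2 = _state_index(Nb)
    n_ssa, n4 = ssa_p.size, p1.size
    n = 1 + n_ssa + 2 * n4

    kinds = np.empty(n, dtype=np.uint8)
    kinds[0] = 0
    kinds[1:1 + n_ssa] = 1
    kinds[1 + n_ssa::2] = 2
    kinds[2 + n_ssa::2] = 3

    islands = np.full((n, 4), -1, dtype=np.int32)
    islands[1:1 + n_ssa, 0] = ssa_p
    islands[1:1 + n_ssa, 1] = ssa_q
    two = np.stack([p1, q1, p2, q2], axis=1)
    islands[1 + n_ssa::2] = two
    islands[2 + n_ssa::2] = two

    return StateEnsemble(partition=partition, params=params, T=float(T),
                         free_energies=dg, kinds=kinds, islands=islands)


# ---------------------------------------------------------------------------
# Heat capacity and calibration


def heat_capacity_curve(partition: BlockPartition, contacts: ContactMap,
                        charges: Optional[ChargeSet], params: ModelParameters,
                        T_grid: Sequence[float]) -> tuple:
    """Heat capacity C_p(T) = 2RT dlnZ/dT + RT^2 d^2lnZ/dT^2 on a T grid.

    Derivatives of ln Z are centered finite differences on the grid.
    Returns (T_grid, Cp) arrays.
    """
    T = np.asarray(T_grid, dtype=float)
    if T.size < 5:
        raise ValueError("T_grid needs at least 5 points")
    if np.any(np.diff(T) <= 0):
        raise ValueError("T_grid must be strictly increasing")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    system = BlockSystem(partition, contacts, charges, params)
    lnZ = system.log_partition_grid(T)
    return T, _cp_from_lnZ(T, lnZ, params.R)


def _cp_from_lnZ(T: np.ndarray, lnZ: np.ndarray, R: float) -> np.ndarray:
    d1 = np.gradient(lnZ, T)
    d2 = np.gradient(d1, T)
    return 2.0 * R * T * d1 + R * T ** 2 * d2


def _refine_extremum(T: np.ndarray, y: np.ndarray, idx: int) -> float:
    """Parabolic refinement of a grid extremum position."""
    if idx <= 0 or idx >= len(T) - 1:
        return float(T[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(T[idx])
    delta = 0.5 * (y0 - y2) / denom
    return float(T[idx] + delta * (T[idx + 1] - T[idx]))


def _cp_calibration_statistic(T: np.ndarray, Cp: np.ndarray) -> float:
    """Position of the Cp peak; with two peaks, of the trough between them."""
    from scipy.signal import find_peaks

    peaks, props = find_peaks(Cp, prominence=0.02 * max(Cp.max() - Cp.min(), 1e-30))
    if len(peaks) >= 2:
        # two highest local maxima; calibrate on the trough between them
        order = np.argsort(props["prominences"])[::-1][:2]
        a, b = sorted(peaks[order[:2]])
        trough = a + int(np.argmin(Cp[a:b + 1]))
        return _refine_extremum(T, -Cp, trough)
    if len(peaks) == 1:
        return _refine_extremum(T, Cp, int(peaks[0]))
    # no interior peak: fall back to the global argmax (grid edge)
    return float(T[int(np.argmax(Cp))])


@dataclass
class CalibrationResult:
    params: ModelParameters
    peak_T: float
    iterations: int
    trajectory: list = field(default_factory=list)  # [(xi, statistic_T)]

    def to_dict(self) -> dict:
        return {"xi": self.params.xi, "peak_T": self.peak_T,
                "iterations": self.iterations,
                "trajectory": [list(t) for t in self.trajectory]}


def calibrate_xi(partition: BlockPartition, contacts: ContactMap,
                 charges: Optional[ChargeSet], params: ModelParameters,
                 target_Tm: float = 333.0, tol: float = 0.5,
                 T_grid: Optional[Sequence[float]] = None,
                 xi_bounds: tuple = (-200.0, -1.0)) -> CalibrationResult:
    """Adjust xi so the heat-capacity peak sits at ``target_Tm``.

    Bracketing plus bisection on the peak position (trough position when the
    curve is bimodal). The melting temperature increases monotonically with
    |xi|, which makes the bisection well posed.
    """
    if T_grid is None:
        lo = min(250.0, target_Tm - 60.0)
        hi = max(420.0, target_Tm + 60.0)
        T_grid = np.arange(lo, hi + 1e-9, 1.0)
    T_grid = np.asarray(T_grid, dtype=float)
    if not T_grid[0] < target_Tm < T_grid[-1]:
        raise CalibrationError("target_Tm must lie inside the scanned T range")

    trajectory = []
    system = BlockSystem(partition, contacts, charges, params)

    def statistic(xi: float) -> float:
        lnZ = system.log_partition_grid(T_grid, xi=xi)
        stat = _cp_calibration_statistic(T_grid, _cp_from_lnZ(T_grid, lnZ, params.R))
        trajectory.append((xi, stat))
        return stat

    xi_lo, xi_hi = xi_bounds  # xi_lo more negative -> higher Tm
    f_lo = statistic(xi_lo) - target_Tm
    if abs(f_lo) <= tol:
        return CalibrationResult(params.with_xi(xi_lo), f_lo + target_Tm,
                                 len(trajectory), trajectory)
    f_hi = statistic(xi_hi) - target_Tm
    if abs(f_hi) <= tol:
        return CalibrationResult(params.with_xi(xi_hi), f_hi + target_Tm,
                                 len(trajectory), trajectory)
    if not (f_lo > 0 > f_hi):
        raise CalibrationError(
            f"cannot bracket Tm={target_Tm} K with xi in [{xi_lo}, {xi_hi}] "
            f"(peak at {f_lo + target_Tm:.1f} K and {f_hi + target_Tm:.1f} K)"
        )
    xi_mid, f_mid = xi_lo, f_lo
    while xi_hi - xi_lo > 1e-4:
        xi_mid = 0.5 * (xi_lo + xi_hi)
        f_mid = statistic(xi_mid) - target_Tm
        if abs(f_mid) <= tol:
            break
        if f_mid > 0:
            xi_lo = xi_mid
        else:
            xi_hi = xi_mid
    if abs(f_mid) > tol:
        raise CalibrationError(
            f"bisection exhausted without reaching |Tm - {target_Tm}| <= {tol} K"
        )
    logger.info("calibrated xi = %.4f J/mol (peak at %.2f K, %d Cp evaluations)",
                xi_mid, f_mid + target_Tm, len(trajectory))
    return CalibrationResult(params.with_xi(xi_mid), f_mid + target_Tm,
                             len(trajectory), trajectory)


def folded_unfolded_dG(partition: BlockPartition, contacts: ContactMap,
                       charges: Optional[ChargeSet], params: ModelParameters,
                       T: float) -> float:
    """dG_FU = -RT ln(Z_F / Z_U) with F/U split at the highest interior barrier
    of the 1D free-energy profile."""
    ens = compute_partition_function(partition, contacts, charges, params, T)
    nfold = ens.n_folded_blocks
    lw = ens.log_weights
    Nb = partition.Nb
    bins = np.array([logsumexp(lw[nfold == b]) if np.any(nfold == b) else -np.inf
                     for b in range(Nb + 1)])
    dG = -ens.RT * bins  # up to an additive constant; only maxima matter
    finite = np.isfinite(dG)
    interior = np.arange(1, Nb)
    interior = interior[finite[interior]]
    barrier_idx = None
    best = -np.inf
    for k in interior:
        if dG[k] >= dG[k - 1] and dG[k] >= dG[k + 1] and dG[k] > best:
            best, barrier_idx = dG[k], k
    if barrier_idx is None:
        raise CalibrationError(
            "1D profile has no interior barrier; supply an explicit F/U cutoff"
        )
    z_u = logsumexp(lw[nfold < barrier_idx])
    z_f = logsumexp(lw[nfold > barrier_idx])
    return float(-ens.RT * (z_f - z_u))


def calibrate_isostable_pair(inactive: tuple, active: tuple,
                             params: ModelParameters, T_iso: float = 310.0,
                             target_Tm: float = 333.0,
                             tol_dG: float = 100.0) -> tuple:
    """xi per structure such that dG_FU is equal across an active/inactive pair.

    ``inactive`` and ``active`` are (partition, contacts, charges) triples of
    the same receptor in its two conformations. The inactive structure is
    first calibrated to ``target_Tm``; the active structure's xi is then
    solved so that both folded-unfolded stabilities agree at ``T_iso`` within
    ``tol_dG`` J/mol. Returns (params_inactive, params_active).
    """
    part_i, cont_i, chg_i = inactive
    part_a, cont_a, chg_a = active
    if part_i.residue_names != part_a.residue_names:
        logger.warning("active and inactive structures have different sequences")

    cal = calibrate_xi(part_i, cont_i, chg_i, params, target_Tm=target_Tm)
    params_i = cal.params
    target = folded_unfolded_dG(part_i, cont_i, chg_i, params_i, T_iso)

    def h(xi: float) -> float:
        """dG_FU difference; downhill profiles map to large sentinels."""
        try:
            return folded_unfolded_dG(part_a, cont_a, chg_a,
                                      params.with_xi(xi), T_iso) - target
        except CalibrationError:
            ens = compute_partition_function(part_a, cont_a, chg_a,
                                             params.with_xi(xi), T_iso)
            nfold = ens.n_folded_blocks
            lw = ens.log_weights
            # barrierless: dominant basin position decides the sign
            dominant = nfold[int(np.argmax(lw))]
            return -1e12 if dominant > part_a.Nb / 2 else 1e12

    xi_lo, xi_hi = -200.0, -1.0   # h increasing in xi (less negative = less stable)
    h_lo, h_hi = h(xi_lo), h(xi_hi)
    if not (h_lo < 0 < h_hi):
        raise CalibrationError("cannot bracket iso-stability condition in xi bounds")
    h_mid = h_lo
    xi_mid = xi_lo
    for _ in range(80):
        xi_mid = 0.5 * (xi_lo + xi_hi)
        h_mid = h(xi_mid)
        if abs(h_mid) <= 0.5 * tol_dG or xi_hi - xi_lo < 1e-9:
            break
        if h_mid < 0:
            xi_lo = xi_mid
        else:
            xi_hi = xi_mid
    if abs(h_mid) > tol_dG:
        raise CalibrationError(f"iso-stability residual {h_mid:.1f} J/mol > {tol_dG}")
    return params_i, params.with_xi(float(xi_mid))


def cp_curve_to_tsv(T: np.ndarray, Cp: np.ndarray) -> str:
    lines = ["T_K\tCp_J_mol_K"]
    for t, c in zip(T, Cp):
        lines.append(f"{t:.3f}\t{c:.6g}")
    return "\n".join(lines) + "\n"
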