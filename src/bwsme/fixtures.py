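"""Deterministic synthetic structures and an independent brute-force oracle.

Everything the test suite needs is generated here with no downloads: ideal
poly-alanine helices, extended chains, packed alpha-helix bundles written as
standard PDB text, compact random toy chains with fabricated side chains, and
a straight-line brute-force enumeration of the two-island microstate ensemble
that shares no code with the vectorized engine.

All generators are byte-reproducible for a fixed spec and seed.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import constants as sc
from scipy.optimize import brentq

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .parameters import ModelParameters
from .structure_io import (Atom, ChargeSet, ContactMap, ProteinStructure,
                           Residue, SS_COIL, SS_HELIX)

# ideal backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0


def _nerf(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    bc = c - b
    bc_n = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_n)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_n)
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg - 180.0)
    d_local = np.array([-bond * math.cos(theta),
                        bond * math.sin(theta) * math.cos(chi),
                        bond * math.sin(theta) * math.sin(chi)])
    return c + d_local[0] * bc_n + d_local[1] * m + d_local[2] * n


def _build_backbone(n: int, phi: float, psi: float, omega: float = 180.0):
    """N/CA/C/O/CB coordinates of an n-residue chain with uniform dihedrals."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    for i in range(1, n):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega))
        C.append(_nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    O, CB = [], []
    for i in range(n):
        psi_i = psi if i < n - 1 else 180.0
        O.append(_nerf(N[i], CA[i], C[i], 1.231, 120.5, psi_i + 180.0))
        CB.append(_nerf(N[i], C[i], CA[i], 1.53, 110.1, -122.6))
    return (np.array(N), np.array(CA), np.array(C), np.array(O), np.array(CB))


def _residues_from_backbone(names, N, CA, C, O, CB, with_cb=True, start_index=1):
    residues = []
    for k, name in enumerate(names):
        atoms = [Atom("N", "N", tuple(N[k])), Atom("CA", "C", tuple(CA[k])),
                 Atom("C", "C", tuple(C[k])), Atom("O", "O", tuple(O[k]))]
        if with_cb and name != "GLY":
            atoms.append(Atom("CB", "C", tuple(CB[k])))
        idx = start_index + k
        residues.append(Residue(index=idx, name=name, author_id=idx, atoms=atoms))
    return residues


def make_ideal_helix(n: int, resname: str = "ALA") -> ProteinStructure:
    """Ideal poly-alanine alpha helix (phi = -57, psi = -47), unlabelled."""
    bb = _build_backbone(n, _HELIX_PHI, _HELIX_PSI)
    return ProteinStructure("A", _residues_from_backbone([resname] * n, *bb))


def make_extended_chain(n: int, resname: str = "GLY") -> ProteinStructure:
    """Fully extended chain (phi = psi = 180), unlabelled."""
    bb = _build_backbone(n, 180.0, 180.0)
    return ProteinStructure("A", _residues_from_backbone([resname] * n, *bb))


# ---------------------------------------------------------------------------
# Helix bundles


@dataclass(frozen=True)
class SyntheticBundleSpec:
    """Recipe for a packed alpha-helix bundle with extended connecting loops."""

    n_helices: int = 7
    helix_length: int = 25
    loop_length: int = 5
    packing_radius: float = 9.0   # Angstrom, helix axes sit on this circle
    seed: int = 1
    jitter: float = 0.0           # optional coordinate noise, <= 0.2 A

    @property
    def n_residues(self) -> int:
        return (self.n_helices * self.helix_length
                + (self.n_helices - 1) * self.loop_length)


def _rotation_between(u, v):
    """Rotation matrix mapping unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees about any axis perpendicular to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    w = np.cross(u, v)
    k = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + k + k @ k / (1.0 + c)


def _arc_points(p0, p1, n_interior, spacing, bulge_dir):
    """Points on a circular arc from p0 to p1 with arc length spacing*(n+1)."""
    chord = p1 - p0
    c = np.linalg.norm(chord)
    s = spacing * (n_interior + 1)
    u = chord / c
    w = bulge_dir - np.dot(bulge_dir, u) * u
    w /= np.linalg.norm(w)
    if s <= c * 1.001:
        ts = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        pts = p0[None, :] + ts[:, None] * chord[None, :]
        tangents = np.tile(u, (n_interior, 1))
        return pts, tangents, w
    theta = brentq(lambda t: math.sin(t / 2.0) / (t / 2.0) - c / s,
                   1e-9, 2.0 * math.pi - 1e-6)
    radius = s / theta
    mid = 0.5 * (p0 + p1)
    center = mid - radius * math.cos(theta / 2.0) * w
    alphas = np.linspace(-theta / 2.0, theta / 2.0, n_interior + 2)[1:-1]
    pts = (center[None, :]
           + radius * (np.cos(alphas)[:, None] * w[None, :]
                       + np.sin(alphas)[:, None] * u[None, :]))
    tangents = (-np.sin(alphas)[:, None] * w[None, :]
                + np.cos(alphas)[:, None] * u[None, :])
    return pts, tangents, w


def _loop_residues(ca_pts, tangents, normal, names, start_index):
    residues = []
    for k in range(len(ca_pts)):
        ca = ca_pts[k]
        t = tangents[k] / np.linalg.norm(tangents[k])
        b = np.cross(t, normal)
        b /= np.linalg.norm(b)
        atoms = [
            Atom("N", "N", tuple(ca - 1.25 * t)),
            Atom("CA", "C", tuple(ca)),
            Atom("C", "C", tuple(ca + 1.25 * t)),
            Atom("O", "O", tuple(ca + 1.25 * t + 1.23 * b)),
            Atom("CB", "C", tuple(ca + 1.53 * normal)),
        ]
        idx = start_index + k
        residues.append(Residue(index=idx, name=names[k], author_id=idx,
                                atoms=atoms))
    return residues


def _bundle_sequence(spec: SyntheticBundleSpec):
    """Helix residues LEU (one LYS in helix 1, one ASP in helix 2), loops SER."""
    names, labels = [], []
    for h in range(spec.n_helices):
        for r in range(spec.helix_length):
            mid = spec.helix_length // 2
            if h == 0 and r == mid:
                names.append("LYS")
            elif h == 1 and r == mid:
                names.append("ASP")
            else:
                names.append("LEU")
            labels.append(SS_HELIX)
        if h < spec.n_helices - 1:
            names.extend(["SER"] * spec.loop_length)
            labels.extend([SS_COIL] * spec.loop_length)
    return names, labels


def bundle_ss_labels(spec: SyntheticBundleSpec):
    """Secondary-structure labels implied by the bundle construction."""
    return _bundle_sequence(spec)[1]


def _build_bundle_residues(spec: SyntheticBundleSpec):
    if spec.n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    names, labels = _bundle_sequence(spec)
    helix_bb = _build_backbone(spec.helix_length, _HELIX_PHI, _HELIX_PSI)
    helix_coords = np.stack(helix_bb)                 # (5, L, 3)
    ca = helix_coords[1]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    centroid = ca.mean(axis=0)

    residues = []
    placed_ca_ends = []
    for h in range(spec.n_helices):
        direction = np.array([0.0, 0.0, 1.0 if h % 2 == 0 else -1.0])
        rot = _rotation_between(axis, direction)
        # per-helix azimuthal phase keeps CB atoms of neighbors from clashing
        phase = math.radians(40.0 * h)
        spin = np.array([[math.cos(phase), -math.sin(phase), 0.0],
                         [math.sin(phase), math.cos(phase), 0.0],
                         [0.0, 0.0, 1.0]])
        angle = 2.0 * math.pi * h / spec.n_helices
        offset = np.array([spec.packing_radius * math.cos(angle),
                           spec.packing_radius * math.sin(angle), 0.0])
        coords = (helix_coords - centroid) @ rot.T @ spin.T + offset
        start = h * (spec.helix_length + spec.loop_length)
        helix_names = names[start:start + spec.helix_length]
        residues.extend(_residues_from_backbone(
            helix_names, *coords, start_index=start + 1))
        placed_ca_ends.append((coords[1][0], coords[1][-1]))

        if h < spec.n_helices - 1:
            # loop from this helix's C-terminal CA toward the next helix
            next_angle = 2.0 * math.pi * (h + 1) / spec.n_helices
            next_offset = np.array([spec.packing_radius * math.cos(next_angle),
                                    spec.packing_radius * math.sin(next_angle), 0.0])
            next_dir = np.array([0.0, 0.0, 1.0 if (h + 1) % 2 == 0 else -1.0])
            next_rot = _rotation_between(axis, next_dir)
            next_phase = math.radians(40.0 * (h + 1))
            next_spin = np.array(
                [[math.cos(next_phase), -math.sin(next_phase), 0.0],
                 [math.sin(next_phase), math.cos(next_phase), 0.0],
                 [0.0, 0.0, 1.0]])
            next_start_ca = ((ca[0] - centroid) @ next_rot.T @ next_spin.T
                             + next_offset)
            p0 = coords[1][-1]
            p1 = next_start_ca
            mid = 0.5 * (p0 + p1)
            z_sign = 1.0 if mid[2] >= 0 else -1.0
            radial = np.array([mid[0], mid[1], 0.0])
            nr = np.linalg.norm(radial)
            radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
            bulge = radial + 0.9 * z_sign * np.array([0.0, 0.0, 1.0])
            bulge /= np.linalg.norm(bulge)
            pts, tans, normal = _arc_points(p0, p1, spec.loop_length, 3.8, bulge)
            loop_start = start + spec.helix_length
            loop_names = names[loop_start:loop_start + spec.loop_length]
            residues.extend(_loop_residues(pts, tans, normal, loop_names,
                                           start_index=loop_start + 1))

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        jit = min(spec.jitter, 0.2)
        for r in residues:
            noise = rng.normal(0.0, jit, size=(len(r.atoms), 3))
            r.atoms = [Atom(a.name, a.element, tuple(np.asarray(a.xyz) + d))
                       for a, d in zip(r.atoms, noise)]

    # clash check: atoms of residues at least two apart in sequence
    all_xyz, res_of = [], []
    for r in residues:
        for a in r.atoms:
            all_xyz.append(a.xyz)
            res_of.append(r.index)
    all_xyz = np.array(all_xyz)
    res_of = np.array(res_of)
    from scipy.spatial import cKDTree
    pairs = cKDTree(all_xyz).query_pairs(r=2.0, output_type="ndarray")
    if pairs.size:
        seq_sep = np.abs(res_of[pairs[:, 0]] - res_of[pairs[:, 1]])
        if np.any(seq_sep >= 2):
            raise ValueError(
                f"packing_radius {spec.packing_radius} A produces steric "
                f"clashes (< 2 A between non-adjacent residues)"
            )
    return residues, labels


def bundle_structure(spec: SyntheticBundleSpec) -> ProteinStructure:
    """The bundle as a labelled :class:`ProteinStructure` (construction labels)."""
    residues, labels = _build_bundle_residues(spec)
    for r, lab in zip(residues, labels):
        r.ss_label = lab
    return ProteinStructure("A", residues)


def _structure_to_pdb_text(structure: ProteinStructure) -> str:
    n_atoms = sum(len(r.atoms) for r in structure.residues)
    array = struc.AtomArray(n_atoms)
    k = 0
    for r in structure.residues:
        for a in r.atoms:
            array.chain_id[k] = structure.chain_id
            array.res_id[k] = r.author_id
            array.res_name[k] = r.name
            array.atom_name[k] = a.name
            array.element[k] = a.element
            array.hetero[k] = False
            array.coord[k] = a.xyz
            k += 1
    f = pdb.PDBFile()
    f.set_structure(array)
    out = io.StringIO()
    f.write(out)
    return out.getvalue()


def make_helix_bundle(spec: SyntheticBundleSpec) -> str:
    """PDB-format text of the synthetic bundle (byte-identical per spec+seed)."""
    return _structure_to_pdb_text(bundle_structure(spec))


def make_stride_annotation(spec: SyntheticBundleSpec) -> str:
    """STRIDE-like ASG records matching the bundle construction."""
    labels = bundle_ss_labels(spec)
    names, _ = _bundle_sequence(spec)
    lines = []
    for i, (name, lab) in enumerate(zip(names, labels), start=1):
        code = "H" if lab == SS_HELIX else "C"
        full = "AlphaHelix" if lab == SS_HELIX else "Coil"
        lines.append(f"ASG  {name} A {i:4d} {i:4d}    {code}   {full:11s} "
                     f"{-57.0:9.2f} {-47.0:9.2f} {0.0:9.1f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Random compact toys (for oracle cross-checks)

_TOY_NAMES = ("LEU", "VAL", "PHE", "LYS", "ASP", "SER", "PRO", "THR")


def make_random_toy(n: int, seed: int, charged: bool = True) -> ProteinStructure:
    """Compact random-walk chain with fabricated side-chain atoms.

    Geometry is a self-avoiding random walk of CA positions (3.8 A steps,
    biased toward the centroid so contacts form), with N/C backbone atoms
    along the walk direction and crude side chains perpendicular to it. One
    lysine and one aspartate are always present when ``charged`` so that the
    electrostatics path is exercised. Labels alternate helix/coil randomly.
    """
    ca = None
    for attempt in range(64):
        rng = np.random.default_rng((seed, attempt))
        walk = [np.zeros(3)]
        ok = True
        while len(walk) < n:
            for _ in range(300):
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                bias = -walk[-1] / (np.linalg.norm(walk[-1]) + 1.0)
                cand = walk[-1] + 3.8 * (0.7 * step + 0.3 * bias)
                if all(np.linalg.norm(cand - p) > 3.4 for p in walk[:-1]):
                    walk.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            ca = np.array(walk)
            break
    if ca is None:
        raise RuntimeError("random toy generation failed to place residues")
    rng = np.random.default_rng((seed, 10_000))

    names = [str(rng.choice(_TOY_NAMES)) for _ in range(n)]
    if charged and n >= 4:
        names[1], names[n - 2] = "LYS", "ASP"
    labels = [SS_HELIX if rng.random() < 0.5 else SS_COIL for _ in range(n)]

    residues = []
    for i in range(n):
        t = (ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)])
        t /= np.linalg.norm(t)
        perp = np.cross(t, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(t, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        atoms = [Atom("N", "N", tuple(ca[i] - 1.25 * t)),
                 Atom("CA", "C", tuple(ca[i])),
                 Atom("C", "C", tuple(ca[i] + 1.25 * t)),
                 Atom("O", "O", tuple(ca[i] + 1.25 * t + 1.23 * perp))]
        name = names[i]
        if name != "GLY":
            cb = ca[i] + 1.53 * perp
            atoms.append(Atom("CB", "C", tuple(cb)))
            if name == "LYS":
                atoms.append(Atom("NZ", "N", tuple(cb + 2.5 * perp)))
            elif name == "ASP":
                atoms.append(Atom("OD1", "O", tuple(cb + 1.5 * perp + 0.6 * t)))
                atoms.append(Atom("OD2", "O", tuple(cb + 1.5 * perp - 0.6 * t)))
            elif name in ("PHE", "LEU", "VAL", "THR"):
                atoms.append(Atom("CG", "C", tuple(cb + 1.5 * perp)))
                atoms.append(Atom("CD1", "C", tuple(cb + 2.2 * perp + 0.7 * t)))
        residues.append(Residue(index=i + 1, name=name, author_id=i + 1,
                                atoms=atoms, ss_label=labels[i]))
    return ProteinStructure("A", residues)


# ---------------------------------------------------------------------------
# Brute-force oracle

_ORACLE_COULOMB = sc.Avogadro * sc.e ** 2 / (4.0 * math.pi * sc.epsilon_0) * 1e10


@dataclass
class BruteForceResult:
    Z: float
    records: list            # (kind, islands 1-based residue ranges, mask, dG, w)
    p: np.ndarray            # residue folding probabilities
    p_ff: np.ndarray         # four sub-ensemble sums, N x N (diagonal NaN)
    p_fu: np.ndarray
    p_uf: np.ndarray
    p_uu: np.ndarray
    dG_plus: np.ndarray
    dG_minus: np.ndarray
    dG_c: np.ndarray
    profile_dG: np.ndarray   # over 0..N folded residues; +inf empty
    T: float


def _mask_islands(mask: int, n: int):
    islands = []
    i = 0
    while i < n:
        if mask >> i & 1:
            j = i
            while j + 1 < n and mask >> (j + 1) & 1:
                j += 1
            islands.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return islands


def brute_force_partition(structure: ProteinStructure, contacts: ContactMap,
                          charges: Optional[ChargeSet], params: ModelParameters,
                          T: float) -> BruteForceResult:
    """Independent enumeration of the <= 2-island ensemble at block size 1.

    Every binary folded/unfolded string over residues is generated directly;
    strings with one island are single states, strings with two islands are
    counted twice (with and without inter-island interactions, the latter
    additionally paying the entropy of fixing the intervening gap). Energies
    are evaluated with straight-line loops sharing nothing with the
    vectorized engine.
    """
    n = len(structure)
    if n > 14:
        raise ValueError("brute force oracle is limited to N <= 14")
    R = params.R
    RT = R * T
    g = (T - params.T_ref) - T * math.log(T / params.T_ref)

    # per-residue entropy
    s_res = []
    for r in structure.residues:
        if r.name == "PRO":
            s_res.append(params.dS_pro)
        else:
            s = params.dS_res
            if r.ss_label == SS_COIL:
                s += params.ddS_coil
            s_res.append(s)

    contact_list = [(i, j, c) for (i, j), c in contacts.items()]
    charge_list = []
    if charges is not None:
        ents = list(charges.entries)
        if params.ionic_strength > 0:
            kappa = math.sqrt(2.0 * sc.Avogadro * sc.e ** 2 * 1000.0
                              * params.ionic_strength
                              / (sc.epsilon_0 * params.dielectric
                                 * sc.Boltzmann * T)) * 1e-10
        else:
            kappa = 0.0
        for x in range(len(ents)):
            for y in range(x + 1, len(ents)):
                e1, e2 = ents[x], ents[y]
                r = math.dist(e1.site_xyz, e2.site_xyz)
                if r == 0.0:
                    continue
                energy = (_ORACLE_COULOMB * e1.charge * e2.charge
                          * math.exp(-kappa * r) / (params.dielectric * r))
                charge_list.append((e1.residue_index, e2.residue_index, energy))

    def state_energy(mask: int, islands, with_loop: bool) -> float:
        island_of = {}
        for k, (a, b) in enumerate(islands):
            for i in range(a, b + 1):
                island_of[i] = k

        def active(i, j):
            if i not in island_of or j not in island_of:
                return False
            if len(islands) == 2 and not with_loop:
                return island_of[i] == island_of[j]
            return True

        e = 0.0
        for i, j, c in contact_list:
            if active(i, j):
                e += c * (params.xi + params.dCp_cont * g)
        for i, j, energy in charge_list:
            if active(i, j):
                e += energy
        s = sum(s_res[i - 1] for i in island_of)
        if with_loop and len(islands) == 2:
            for i in range(islands[0][1] + 1, islands[1][0]):
                s += s_res[i - 1]
        return e - T * s

    records = []
    for mask in range(2 ** n):
        islands = _mask_islands(mask, n)
        if len(islands) == 0:
            records.append(("U", (), mask, 0.0, 1.0))
        elif len(islands) == 1:
            dg = state_energy(mask, islands, with_loop=False)
            records.append(("SSA", tuple(islands), mask, dg, math.exp(-dg / RT)))
        elif len(islands) == 2:
            dg = state_energy(mask, islands, with_loop=False)
            records.append(("DSA", tuple(islands), mask, dg, math.exp(-dg / RT)))
            dg = state_energy(mask, islands, with_loop=True)
            records.append(("DSAwL", tuple(islands), mask, dg, math.exp(-dg / RT)))

    Z = sum(w for *_, w in records)

    p = np.zeros(n)
    for kind, islands, mask, dg, w in records:
        for i in range(n):
            if mask >> i & 1:
                p[i] += w / Z

    p_ff = np.zeros((n, n))
    p_fu = np.zeros((n, n))
    p_uf = np.zeros((n, n))
    p_uu = np.zeros((n, n))
    for kind, islands, mask, dg, w in records:
        for i in range(n):
            fi = mask >> i & 1
            for j in range(n):
                fj = mask >> j & 1
                if fi and fj:
                    p_ff[i, j] += w / Z
                elif fi:
                    p_fu[i, j] += w / Z
                elif fj:
                    p_uf[i, j] += w / Z
                else:
                    p_uu[i, j] += w / Z

    floor = 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        dg_plus = RT * np.log(np.maximum(p_ff, floor) / np.maximum(p_uf, floor))
        dg_minus = RT * np.log(np.maximum(p_fu, floor) / np.maximum(p_uu, floor))
    dg_c = dg_plus - dg_minus
    for m in (p_ff, p_fu, p_uf, p_uu, dg_plus, dg_minus, dg_c):
        np.fill_diagonal(m, np.nan)

    z_bins = [0.0] * (n + 1)
    for kind, islands, mask, dg, w in records:
        z_bins[bin(mask).count("1")] += w
    profile = np.array([-RT * math.log(z / Z) if z > 0 else math.inf
                        for z in z_bins])

    return BruteForceResult(Z=Z, records=records, p=p, p_ff=p_ff, p_fu=p_fu,
                            p_uf=p_uf, p_uu=p_uu, dG_plus=dg_plus,
                            dG_minus=dg_minus, dG_c=dg_c, profile_dG=profile,
                            T=T)
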