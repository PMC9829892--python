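"""In-silico alanine scanning through ensemble perturbation.

A mutation to alanine is modelled as a side-chain truncation past C-beta on
the wild-type coordinates: every native contact contributed by the site's
atoms beyond C-beta is removed, and the site's side-chain charge (if any) is
dropped; every other input and all model parameters stay identical to the
wild type. For each mutated site the ensemble is rebuilt, the positive
coupling matrix dG_+ recomputed and referenced to the wild-type matrix; the
difference averaged across the partner dimension gives the per-residue
response vector <ddG_+>. Only dG_+ is differenced: it reports on the states
that harbor coupled residues in the native ensemble.

This truncation protocol is a deterministic approximation to rebuilding the
mutant side chain with a modelling tool: it can only remove contacts, never
gain the few new ones a rebuilt methyl group might make.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coupling import coupling_free_energies
from .ensemble_core import BlockPartition, ModelParameters, compute_partition_function
from .structure_io import (ChargeSet, ContactMap, ProteinStructure, Residue,
                           compute_contacts)

logger = logging.getLogger(__name__)

#: Atoms kept at the mutated site (alanine heavy atoms plus terminal oxygen).
_KEPT_ATOMS = {"N", "CA", "C", "O", "CB", "OXT"}

#: Residues never scanned by default.
_SKIP_RESIDUES = {"ALA", "GLY", "PRO"}


@dataclass
class MutationalResponse:
    """N x m matrix of <ddG_+> response vectors, one column per mutated site."""

    ddG_plus_matrix: np.ndarray      # (N, m), J/mol
    mutated_sites: list              # residue indices, length m
    mu: np.ndarray                   # per-residue mean over mutants
    sigma: np.ndarray                # per-residue sd over mutants
    T: float
    n_ensemble_evaluations: int = 0
    failed_sites: list = None

    @property
    def m(self) -> int:
        return len(self.mutated_sites)

    def column(self, site: int) -> np.ndarray:
        if site not in self.mutated_sites:
            raise ValueError(f"site {site} was not scanned")
        return self.ddG_plus_matrix[:, self.mutated_sites.index(site)]

    def to_tsv(self) -> str:
        lines = ["residue\tmu_kJ\tsigma_kJ"]
        for i, (m, s) in enumerate(zip(self.mu, self.sigma), start=1):
            lines.append(f"{i}\t{m / 1000.0:.6g}\t{s / 1000.0:.6g}")
        return "\n".join(lines) + "\n"

    def matrix_csv(self) -> str:
        header = "residue," + ",".join(f"site_{s}" for s in self.mutated_sites)
        lines = [header]
        for i in range(self.ddG_plus_matrix.shape[0]):
            row = ",".join(f"{v / 1000.0:.6g}" for v in self.ddG_plus_matrix[i])
            lines.append(f"{i + 1},{row}")
        return "\n".join(lines) + "\n"


def truncate_to_alanine(structure: ProteinStructure, contacts: ContactMap,
                        charges: Optional[ChargeSet],
                        site: int) -> tuple:
    """Contact map and charge set of the site's alanine-truncation mutant.

    Contacts contributed by the site's atoms beyond C-beta are removed by
    recomputing the map on the truncated coordinates (identical geometry
    otherwise, so all other pairs are unchanged). The site's side-chain
    charge entry is dropped; terminal charges are backbone features and stay.
    """
    residues = {r.index: r for r in structure.residues}
    if site not in residues:
        raise ValueError(f"site {site} not in structure (1..{len(structure)})")
    res = residues[site]
    if res.name in _SKIP_RESIDUES:
        logger.warning("site %d is %s; truncation is a null perturbation",
                       site, res.name)
    kept = [a for a in res.atoms if a.name in _KEPT_ATOMS]
    new_residues = [r if r.index != site
                    else Residue(r.index, r.name, r.author_id, kept, r.ss_label)
                    for r in structure.residues]
    mutant = ProteinStructure(structure.chain_id, new_residues)
    new_contacts = compute_contacts(mutant, cutoff=contacts.cutoff)
    new_charges = charges.without_sidechain(site) if charges is not None else None
    return new_contacts, new_charges


def alanine_scan(structure: ProteinStructure, partition: BlockPartition,
                 contacts: ContactMap, charges: Optional[ChargeSet],
                 params: ModelParameters, T: float,
                 sites: Optional[Sequence[int]] = None) -> MutationalResponse:
    """Scan alanine substitutions and collect <ddG_+> response vectors.

    Default sites are all residues except alanine, glycine and proline. The
    wild-type dG_+ matrix is computed once and shared; the scan of m sites
    costs exactly m + 1 ensemble evaluations. Per-site failures are logged
    and the column dropped rather than aborting the scan.
    """
    if sites is None:
        sites = [r.index for r in structure.residues
                 if r.name not in _SKIP_RESIDUES]
    sites = list(sites)

    n_eval = 0
    ens_wt = compute_partition_function(partition, contacts, charges, params, T)
    n_eval += 1
    wt_plus = coupling_free_energies(ens_wt).dG_plus

    n = len(structure)
    columns = []
    ok_sites = []
    failed = []
    for site in sites:
        try:
            mut_contacts, mut_charges = truncate_to_alanine(
                structure, contacts, charges, site)
            ens_mut = compute_partition_function(
                partition, mut_contacts, mut_charges, params, T)
            n_eval += 1
            mut_plus = coupling_free_energies(ens_mut).dG_plus
            ddg = mut_plus - wt_plus
            with np.errstate(invalid="ignore"):
                col = np.nanmean(ddg, axis=1)
            columns.append(col)
            ok_sites.append(site)
        except Exception as exc:  # per-site failure: drop column, keep scanning
            logger.error("alanine scan failed at site %d: %s", site, exc)
            failed.append(site)

    if columns:
        matrix = np.stack(columns, axis=1)
        mu = matrix.mean(axis=1)
        sigma = matrix.std(axis=1)
    else:
        matrix = np.empty((n, 0))
        mu = np.full(n, np.nan)
        sigma = np.full(n, np.nan)
    return MutationalResponse(ddG_plus_matrix=matrix, mutated_sites=ok_sites,
                              mu=mu, sigma=sigma, T=T,
                              n_ensemble_evaluations=n_eval, failed_sites=failed)


def response_vs_distance(response: MutationalResponse,
                         structure: ProteinStructure, site: int) -> np.ndarray:
    """(CA-distance from the mutated site, <ddG_+>) pairs, sorted by distance.

    Returns an (N, 2) array; the mutated site itself appears at distance 0.
    """
    col = response.column(site)
    ca = structure.ca_coords()
    d = np.linalg.norm(ca - ca[site - 1], axis=1)
    order = np.argsort(d, kind="stable")
    return np.stack([d[order], col[order]], axis=1)


def distance_profile_tsv(profile: np.ndarray) -> str:
    lines = ["ca_distance_A\tddG_plus_kJ"]
    for d, v in profile:
        lines.append(f"{d:.3f}\t{v / 1000.0:.6g}")
    return "\n".join(lines) + "\n"
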