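"""Energy-function parameters of the block WSME model.

The model is native-centric: every native heavy-atom contact contributes a
van der Waals energy ``xi`` plus a contact-scaled solvation (heat-capacity)
term, ionizable groups interact through screened Debye-Hueckel electrostatics,
and fixing a residue in its native conformation costs conformational entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class ModelParameters:
    """All tunable constants of the bWSME energy function.

    Attributes
    ----------
    xi : float
        van der Waals interaction energy per native heavy-atom contact,
        J mol^-1 (negative, stabilizing). Calibrated per structure so the
        heat-capacity peak falls at ``333 K`` by default; the cross-protein
        mean reported for GPCR-scale systems is about -49 J mol^-1.
    dCp_cont : float
        Heat-capacity change per native contact, J mol^-1 K^-1.
    dS_res : float
        Conformational entropy cost of fixing one residue, J mol^-1 K^-1.
    ddS_coil : float
        Excess entropic penalty for residues in coil regions, J mol^-1 K^-1.
    dS_pro : float
        Total entropic penalty for proline residues (restricted backbone).
    dielectric : float
        Uniform effective dielectric constant (low value mimics the membrane
        interior).
    ionic_strength : float
        Molar ionic strength entering the Debye screening length.
    T_ref : float
        Reference temperature of the solvation free energy, K.
    R : float
        Gas constant, J mol^-1 K^-1.
    block_size : int
        Number of consecutive residues grouped into one folding unit.
    """

    xi: float = -48.9
    dCp_cont: float = -0.36
    dS_res: float = -10.0
    ddS_coil: float = -6.1
    dS_pro: float = 0.0
    dielectric: float = 4.0
    ionic_strength: float = 0.1
    T_ref: float = 385.0
    R: float = field(default=R_GAS)
    block_size: int = 4

    def __post_init__(self) -> None:
        if not self.xi < 0:
            raise ValueError(f"xi must be negative (got {self.xi})")
        if self.dCp_cont > 0:
            raise ValueError(f"dCp_cont must be <= 0 (got {self.dCp_cont})")
        if not self.dS_res < 0:
            raise ValueError(f"dS_res must be negative (got {self.dS_res})")
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1 (got {self.block_size})")
        if not self.dielectric > 0:
            raise ValueError(f"dielectric must be positive (got {self.dielectric})")

    def with_xi(self, xi: float) -> "ModelParameters":
        return replace(self, xi=xi)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)
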