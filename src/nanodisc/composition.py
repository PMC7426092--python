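"""Chemical composition and scattering-length-density (contrast) calculations.

Each nanodisc component (lipid headgroups, lipid tails, the two scaffold-protein
belts, optional His/TEV purification tags) is described by a chemical formula and
a molecular volume.  Excess scattering length densities for X-rays and neutrons
are computed from tabulated atomic scattering lengths relative to the solvent
(H2O or D2O), which is the contrast information the absolute-scale model needs.

Units: scattering lengths in fm (1 fm = 1e-13 cm), volumes in A^3, scattering
length densities in fm/A^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# Thomson scattering length of one electron, fm.
R_ELECTRON_FM = 2.8179403

# Coherent neutron scattering lengths, fm (Sears, Neutron News 3, 1992).
NEUTRON_B_FM = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "P": 5.13,
    "S": 2.847,
}

ATOMIC_NUMBER = {"H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}

# Molecular volume of one water molecule, A^3 (0.334 e/A^3 electron density).
V_WATER = 29.94


class UnknownElementError(ValueError):
    """Formula contains an element outside the supported set."""


def _check_formula(formula: dict[str, float]) -> None:
    for el in formula:
        if el not in ATOMIC_NUMBER:
            raise UnknownElementError(f"unsupported element {el!r}")


def xray_b(formula: dict[str, float]) -> float:
    """Total X-ray scattering length of a formula unit, fm."""
    _check_formula(formula)
    return R_ELECTRON_FM * sum(n * ATOMIC_NUMBER[el] for el, n in formula.items())


def neutron_b(formula: dict[str, float]) -> float:
    """Total coherent neutron scattering length of a formula unit, fm."""
    _check_formula(formula)
    return sum(n * NEUTRON_B_FM[el] for el, n in formula.items())


@dataclass(frozen=True)
class Component:
    """One chemical component: formula, volume, and H/D exchange bookkeeping.

    ``n_exchangeable`` counts labile hydrogens (already included in the formula
    as H) that trade with solvent deuterons in D2O.
    """

    name: str
    formula: dict[str, float]
    volume: float  # A^3
    n_exchangeable: float = 0.0

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError(f"component {self.name}: volume must be positive")
        _check_formula(self.formula)


def average_protein_residues(n_res: float, volume: float) -> Component:
    """Generic protein component from an average amino-acid composition.

    Per residue: C4.9 H7.8 N1.4 O1.5 S0.04 with ~1.6 labile hydrogens
    (backbone amide plus polar side chains).  Gives the typical protein
    electron density of ~0.43 e/A^3 at ~136 A^3 per residue.
    """
    f = {"C": 4.9 * n_res, "H": 7.8 * n_res, "N": 1.4 * n_res,
         "O": 1.5 * n_res, "S": 0.04 * n_res}
    return Component("protein", f, volume, n_exchangeable=1.6 * n_res)


# DMPC split into headgroup (phosphocholine + glycerol backbone) and the two
# myristoyl tails; the head volume of 330 A^3 is the standard PC value, the
# total DMPC volume is 1085 A^3.
V_DMPC = 1085.0
V_HEAD = 330.0

DMPC_HEAD = Component("dmpc-head", {"C": 10, "H": 18, "N": 1, "O": 8, "P": 1}, V_HEAD)
DMPC_TAILS = Component("dmpc-tails", {"C": 26, "H": 54}, V_DMPC - V_HEAD)

# Scaffold-belt variants: volumes per belt.  Residue counts are nominal and
# only set the generic-protein formula scale.
V_BELT_DH5 = 24298.0
V_BELT_DH4H5 = 20349.0
V_TAG = 3142.0

BELT_DH5 = replace(average_protein_residues(178.0, V_BELT_DH5), name="belt-dh5")
BELT_DH4H5 = replace(average_protein_residues(149.0, V_BELT_DH4H5), name="belt-dh4h5")
HIS_TAG = replace(average_protein_residues(23.0, V_TAG), name="his-tev-tag")


@dataclass(frozen=True)
class MolecularComposition:
    """Full chemical composition of a nanodisc.

    Invariant: head.volume + tails.volume equals the whole-lipid volume.
    """

    head: Component = DMPC_HEAD
    tails: Component = DMPC_TAILS
    belt: Component = BELT_DH5
    tag: Component = HIS_TAG
    n_belt: int = 2
    n_tag: int = 0

    @property
    def v_lipid(self) -> float:
        return self.head.volume + self.tails.volume


@dataclass(frozen=True)
class ContrastSet:
    """Excess scattering length densities (fm/A^3) for one radiation/solvent."""

    contrast: str  # "xray" | "neutron"
    solvent: str  # "h2o" | "d2o"
    sld_solvent: float
    excess: dict[str, float] = field(default_factory=dict)  # per component name

    def __getitem__(self, name: str) -> float:
        return self.excess[name]


def solvent_sld(contrast: str, solvent: str) -> float:
    """Scattering length density of the solvent, fm/A^3."""
    formula = {"H": 2, "O": 1} if solvent == "h2o" else {"D": 2, "O": 1}
    b = xray_b(formula) if contrast == "xray" else neutron_b(formula)
    return b / V_WATER


def component_sld(
    comp: Component, contrast: str, solvent: str, exchange_fraction: float = 0.9
) -> float:
    """Excess SLD of one component: (sum of b)/volume minus the solvent SLD.

    In D2O a fraction ``exchange_fraction`` of the labile hydrogens are
    replaced by deuterium for the neutron case.
    """
    if contrast not in ("xray", "neutron"):
        raise ValueError(f"unknown contrast {contrast!r}")
    if solvent not in ("h2o", "d2o"):
        raise ValueError(f"unknown solvent {solvent!r}")
    formula = dict(comp.formula)
    if contrast == "neutron" and solvent == "d2o" and comp.n_exchangeable > 0:
        moved = exchange_fraction * comp.n_exchangeable
        formula["H"] = formula.get("H", 0.0) - moved
        formula["D"] = formula.get("D", 0.0) + moved
    b = xray_b(formula) if contrast == "xray" else neutron_b(formula)
    return b / comp.volume - solvent_sld(contrast, solvent)


def component_slds(
    composition: MolecularComposition,
    contrast: str,
    solvent: str,
    exchange_fraction: float = 0.9,
) -> ContrastSet:
    """Excess SLDs of every component of a composition for one contrast."""
    comps = {
        "head": composition.head,
        "tails": composition.tails,
        "belt": composition.belt,
        "tag": composition.tag,
    }
    excess = {
        key: component_sld(c, contrast, solvent, exchange_fraction)
        for key, c in comps.items()
    }
    return ContrastSet(
        contrast=contrast,
        solvent=solvent,
        sld_solvent=solvent_sld(contrast, solvent),
        excess=excess,
    )
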