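"""Molecular-constraint geometry of the elliptical nanodisc model.

The disc is a stack of flat elliptical layers (hydrophobic tail core sandwiched
between two headgroup layers) encircled by a hollow elliptical cylinder that
models the two stacked scaffold-protein belts.  All layer dimensions follow
from the fit parameters and the molecular volumes:

    pi * R_major * R_minor = (N_lipid / 2) * A_head,   R_major = eps * R_minor
    H_tails = 2 * CV_lipid * v_tails / A_head
    D_head  = CV_lipid * v_head / A_head
    H_lipid = H_tails + 2 * D_head = 2 * CV_lipid * v_lipid / A_head
    pi * H_belt * [(R_major + W)(R_minor + W) - R_major R_minor] = 2 * CV_belt * v_belt

where W (the belt width) is the positive root of the last (quadratic)
constraint: the hollow cylinder of total height H_belt holds the volume of the
two belts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .composition import MolecularComposition


@dataclass
class NanodiscParams:
    """Fit parameters of the molecular-constrained nanodisc model.

    Lengths in A, areas in A^2.  ``scale_xray``/``scale_neutron`` multiply the
    absolute-scale model intensity; ``background`` is per-dataset, in 1/cm.
    ``sigma_r`` is the interface roughness and ``sigma_lip`` the relative
    standard deviation of a normally distributed lipid number (0 = mono-
    disperse).  ``rg_tag`` is the Gaussian-coil radius of gyration used for
    disordered purification tags.
    """

    a_head: float = 54.0
    eps: float = 1.2
    n_lipid: float = 100.0
    cv_belt: float = 1.0
    cv_lipid: float = 1.0
    h_belt: float = 24.0
    scale_xray: float = 1.0
    scale_neutron: float = 1.0
    background: float = 0.0
    sigma_r: float = 2.0
    rg_tag: float = 12.7
    sigma_lip: float = 0.0

    def validate(self) -> None:
        if self.eps < 1:
            raise ValueError("axis ratio eps must be >= 1")
        if self.a_head <= 0:
            raise ValueError("area per headgroup must be positive")
        if self.n_lipid <= 0:
            raise ValueError("lipid number must be positive")
        if self.sigma_lip < 0:
            raise ValueError("sigma_lip must be non-negative")
        if self.h_belt <= 0:
            raise ValueError("belt height must be positive")


@dataclass(frozen=True)
class DerivedDimensions:
    """Geometry derived from the molecular constraints (all lengths in A)."""

    r_major: float
    r_minor: float
    h_lipid: float
    h_tails: float
    d_head: float
    w_belt: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R_major": self.r_major,
            "R_minor": self.r_minor,
            "H_lipid": self.h_lipid,
            "H_tails": self.h_tails,
            "D_head": self.d_head,
            "W_belt": self.w_belt,
        }


class BeltVolumeError(ValueError):
    """Belt volume too small for a positive belt width."""


def belt_width(r_major: float, r_minor: float, h_belt: float, v_belt_total: float) -> float:
    """Positive root W of pi*H*[(a+W)(b+W) - a*b] = V_belt_total."""
    c = v_belt_total / (math.pi * h_belt)
    # W^2 + (a+b) W - c = 0
    disc = (r_major + r_minor) ** 2 + 4.0 * c
    w = 0.5 * (-(r_major + r_minor) + math.sqrt(disc))
    if w <= 0:
        raise BeltVolumeError("belt volume does not admit a positive belt width")
    return w


def derive_dimensions(
    params: NanodiscParams, composition: MolecularComposition | None = None
) -> DerivedDimensions:
    """Resolve the molecular constraints into disc dimensions."""
    comp = composition if composition is not None else MolecularComposition()
    params.validate()
    area = 0.5 * params.n_lipid * params.a_head  # ellipse area, pi*a*b
    r_minor = math.sqrt(area / (math.pi * params.eps))
    r_major = params.eps * r_minor
    h_tails = 2.0 * params.cv_lipid * comp.tails.volume / params.a_head
    d_head = params.cv_lipid * comp.head.volume / params.a_head
    h_lipid = h_tails + 2.0 * d_head
    v_belt_total = 2.0 * params.cv_belt * comp.belt.volume
    w = belt_width(r_major, r_minor, params.h_belt, v_belt_total)
    return DerivedDimensions(r_major, r_minor, h_lipid, h_tails, d_head, w)
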