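"""Channel setup, units and the nondimensional scaling of RT-DC stress.

The quasi-stationary shape of a fluid vesicle in an RT-DC channel is set by a
single dimensionless group, ``K_hat = K * L**2 / (eta * Q)``: the area
expansion modulus ``K`` (N/m) measured against the viscous modulus scale
``eta * Q / L**2`` of the channel (side length ``L``, flow rate ``Q``, buffer
viscosity ``eta``).  Every calibrated fit in this package is expressed in
``K_hat`` and the relative projected area ``A_hat = A / L**2``, which is what
makes the extraction universal across flow rates, channel sizes and buffer
viscosities: results obtained at one setup transfer to another by multiplying
moduli with ``(eta*Q*L_from**2) / (eta'*Q'*L_to**2)`` and areas with
``(L_from/L_to)**2``.

Internal units are SI throughout; micrometres and microlitres appear only at
I/O boundaries (``from_lab_units`` and the CLI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

__all__ = [
    "ChannelSetup",
    "CapillaryInputs",
    "REFERENCE_SETUP",
    "nondim_K",
    "dim_K",
    "nondim_area",
    "rescale_K",
    "rescale_area",
    "capillary_numbers",
    "equivalent_radius",
    "viscosity_lookup",
]

#: Ratio between the equivalent cylindrical channel radius and the square
#: channel side length (10.94 um for a 20 um channel).  Used only for
#: diagnostics such as the centerline Poiseuille velocity.
EQUIVALENT_RADIUS_RATIO = 10.94 / 20.0

#: Approximate shear rate (1/s) at the reference setup; scaled with Q/L**3
#: for other setups.  A diagnostic quantity, not part of the calibration.
REFERENCE_SHEAR_RATE = 35_000.0

#: Effective viscosities (Pa s) of the standard methylcellulose-PBS
#: measurement buffer (0.59% MC-PBS, "CellCarrier B") at the flow rates used
#: in 20 um channels.  The buffer shear-thins, so the effective viscosity
#: depends on the flow rate; entries are tabulated values, keyed by flow rate
#: in m^3/s.  Unknown (medium, Q) pairs require an explicit user viscosity.
_VISCOSITY_TABLE: dict[str, dict[float, float]] = {
    "cellcarrier b": {
        0.04e-9: 6.3e-3,
        0.08e-9: 4.7e-3,
    },
}


def viscosity_lookup(flow_rate: float, medium: str) -> float:
    """Tabulated effective buffer viscosity in Pa s.

    Parameters
    ----------
    flow_rate
        Flow rate in m^3/s.
    medium
        Buffer label, e.g. ``"CellCarrier B"`` (case-insensitive).

    Raises
    ------
    ConfigurationError
        If the medium or the (medium, flow rate) pair is not tabulated.
    """
    table = _VISCOSITY_TABLE.get(medium.strip().lower())
    if table is None:
        raise ConfigurationError(
            f"no viscosity table for medium {medium!r}; supply viscosity explicitly"
        )
    for q, eta in table.items():
        if math.isclose(q, flow_rate, rel_tol=1e-3):
            return eta
    raise ConfigurationError(
        f"no tabulated viscosity for medium {medium!r} at Q={flow_rate:g} m^3/s; "
        "supply viscosity explicitly"
    )


def equivalent_radius(channel_length: float) -> float:
    """Equivalent cylindrical channel radius (m) for a square side length (m)."""
    if channel_length <= 0:
        raise ValueError("channel length must be positive")
    return EQUIVALENT_RADIUS_RATIO * channel_length


@dataclass(frozen=True)
class ChannelSetup:
    """Experimental context defining the stress and modulus scales.

    Parameters
    ----------
    channel_length
        Side length L of the square channel cross-section, in m.
    flow_rate
        Imposed flow rate Q, in m^3/s.
    viscosity
        Effective buffer viscosity eta, in Pa s.
    pixel_size
        Camera resolution, m per pixel (default 340 nm).
    """

    channel_length: float = 20e-6
    flow_rate: float = 0.04e-9
    viscosity: float = 0.015
    pixel_size: float = 0.34e-6

    def __post_init__(self) -> None:
        for name in ("channel_length", "flow_rate", "viscosity", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_lab_units(
        cls,
        channel_um: float = 20.0,
        flow_ul_s: float = 0.04,
        viscosity_mpa_s: float | None = None,
        medium: str | None = None,
        pixel_um: float = 0.34,
    ) -> "ChannelSetup":
        """Build a setup from the units used at the instrument.

        Either ``viscosity_mpa_s`` or a tabulated ``medium`` label must be
        given; an explicit viscosity always wins.
        """
        flow_rate = flow_ul_s * 1e-9
        if viscosity_mpa_s is not None:
            eta = viscosity_mpa_s * 1e-3
        elif medium is not None:
            eta = viscosity_lookup(flow_rate, medium)
        else:
            raise ConfigurationError("supply viscosity_mpa_s or a medium label")
        return cls(
            channel_length=channel_um * 1e-6,
            flow_rate=flow_rate,
            viscosity=eta,
            pixel_size=pixel_um * 1e-6,
        )

    @property
    def modulus_scale(self) -> float:
        """eta*Q/L**2 in N/m — the scale against which K is measured."""
        return self.viscosity * self.flow_rate / self.channel_length**2

    @property
    def stress_scale(self) -> float:
        """eta*Q/L**3 in Pa."""
        return self.viscosity * self.flow_rate / self.channel_length**3

    @property
    def equivalent_radius(self) -> float:
        """Equivalent cylindrical channel radius R in m."""
        return equivalent_radius(self.channel_length)

    @property
    def centerline_velocity(self) -> float:
        """Poiseuille centerline velocity 2Q/(pi R**2) in m/s (diagnostic)."""
        return 2.0 * self.flow_rate / (math.pi * self.equivalent_radius**2)

    @property
    def shear_rate(self) -> float:
        """Approximate wall shear rate in 1/s, scaled from the reference setup
        proportionally to Q/L**3."""
        ref = REFERENCE_SETUP
        return REFERENCE_SHEAR_RATE * (
            (self.flow_rate / ref.flow_rate)
            * (ref.channel_length / self.channel_length) ** 3
        )


#: The setup at which the calibration simulations were run:
#: Q' = 0.04 uL/s, L' = 20 um, eta' = 0.015 Pa s.
REFERENCE_SETUP = ChannelSetup(
    channel_length=20e-6, flow_rate=0.04e-9, viscosity=0.015
)


def nondim_K(K, setup: ChannelSetup):
    """K_hat = K * L**2 / (eta*Q) for K in N/m."""
    return K / setup.modulus_scale


def dim_K(K_hat, setup: ChannelSetup):
    """Inverse of :func:`nondim_K`; returns K in N/m."""
    return K_hat * setup.modulus_scale


def nondim_area(area_um2, setup: ChannelSetup):
    """A_hat = A / L**2 for projected areas given in um^2."""
    return area_um2 * 1e-12 / setup.channel_length**2


def rescale_K(K, setup_from: ChannelSetup, setup_to: ChannelSetup):
    """Transfer a modulus measured at one setup to another.

    Multiplies K by ``(eta_to*Q_to*L_from**2) / (eta_from*Q_from*L_to**2)``,
    which leaves K_hat invariant.
    """
    return K * (setup_to.modulus_scale / setup_from.modulus_scale)


def rescale_area(area, setup_from: ChannelSetup, setup_to: ChannelSetup):
    """Companion area rescaling: multiplies areas by (L_from/L_to)**2.

    Unit-agnostic (works identically on um^2 and m^2 values).
    """
    return area * (setup_from.channel_length / setup_to.channel_length) ** 2


@dataclass(frozen=True)
class CapillaryInputs:
    """Inputs for capillary-number diagnostics.

    Parameters
    ----------
    radius
        Vesicle radius r in m.
    shear_rate
        Approximate shear rate in 1/s; when None the setup's scaled estimate
        is used.
    bending_rigidity
        Membrane bending rigidity kappa in N m (default 1e-19, typical GUV).
    """

    radius: float
    shear_rate: float | None = None
    bending_rigidity: float = 1e-19

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.bending_rigidity <= 0:
            raise ValueError("radius and bending rigidity must be positive")
        if self.shear_rate is not None and self.shear_rate <= 0:
            raise ValueError("shear rate must be positive")


def capillary_numbers(
    inputs: CapillaryInputs, K: float, setup: ChannelSetup
) -> tuple[float, float]:
    """(Ca, Ca_kappa) diagnostics for a vesicle of modulus K (N/m).

    ``Ca = eta * gamma_dot * r / K`` measures viscous stress against the
    membrane's resistance to area expansion; ``Ca_kappa = eta * gamma_dot *
    r**3 / kappa`` is the bending-rigidity analogue.  Ca_kappa >> 1 (values
    above 1e5 at typical GUV parameters) indicates that bending contributions
    are negligible and deformation is area-dilatational.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    gdot = inputs.shear_rate if inputs.shear_rate is not None else setup.shear_rate
    ca = setup.viscosity * gdot * inputs.radius / K
    ca_kappa = setup.viscosity * gdot * inputs.radius**3 / inputs.bending_rigidity
    return ca, ca_kappa
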