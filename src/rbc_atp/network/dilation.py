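"""Conducted vasodilation signal summarizing the capillary ATP field.

ATP binding to endothelial purinergic receptors initiates a hyperpolarization
that is conducted upstream along the vessel wall and attenuates exponentially
with distance.  The aggregate signal reaching the arteriolar (upstream) end
of the network is summarized as

    sigma_dilation = sum_i [ATP]_i * exp(-(L - z_i) / lambda)

over segments, with [ATP]_i the segment mean concentration in mol/cm^3, z_i
the segment midpoint on the arterio-venous axis, L the arterio-venous span
and lambda the conduction attenuation length (default 1 cm, far larger than a
capillary network, so sigma is close to the plain sum of segment means).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CapillaryNetwork
from .grid import ATPField
from .transport import UM_TO_MOL_CM3

__all__ = ["DilationSignal", "dilation_signal"]

CONVENTION = "segment-midpoint z on arterio-venous axis; [ATP] in mol/cm^3"


@dataclass(frozen=True)
class DilationSignal:
    sigma: float          # mol/cm^3, summed over segments
    lambda_cm: float
    convention: str = CONVENTION


def dilation_signal(
    field: ATPField,
    network: CapillaryNetwork | None = None,
    lambda_cm: float = 1.0,
) -> DilationSignal:
    """Exponentially attenuated sum of segment-mean [ATP] values.

    sigma is bounded above by the unattenuated sum (lambda -> infinity).
    """
    if lambda_cm <= 0:
        raise ValueError(f"lambda must be > 0 cm, got {lambda_cm}")
    if network is None:
        network = field.grid.network
    means_mol = field.segment_means() * UM_TO_MOL_CM3
    z_cm = np.array([s.z_mid_um for s in network.segments]) * 1e-4
    l_cm = network.l_av_um * 1e-4
    sigma = float(np.sum(means_mol * np.exp(-(l_cm - z_cm) / lambda_cm)))
    return DilationSignal(sigma=sigma, lambda_cm=lambda_cm)
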