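"""Published ST-LCM fitted to the Veneto radon-flux case study.

The four coregionalized variables are monthly radon flux (``rn_flux``, in
kBq m^-2 s^-1), mean air temperature (``tm``, degC), minimum humidity
(``hm``, %) and reference evapotranspiration (``et0``, mm) over the Veneto
region, January 2006 - April 2022.  The constructors below reproduce the
published four-component fit (product-sum parameters, coregionalization
matrices and the joint-diagonalization rotation) and the one-component
intrinsic contender, so they can be evaluated, serialized and used as inputs
without access to the original station data.
"""

from __future__ import annotations

import numpy as np

from .covariance import STLCM, ExponentialMarginal, ProductSumComponent

__all__ = [
    "VARIABLES",
    "PSI",
    "RISK_THRESHOLDS",
    "veneto_fitted_model",
    "veneto_intrinsic_model",
]

VARIABLES = ("rn_flux", "tm", "hm", "et0")

#: orthogonal rotation found by jointly diagonalizing the 120 sample
#: covariance matrices of the four residual variables
PSI = np.array(
    [
        [0.92644863, -0.34811734, 0.14315315, 0.003798338],
        [0.36544978, 0.91846172, -0.12952119, -0.078094773],
        [-0.08630179, 0.17383656, 0.98088864, 0.013795947],
        [0.02629437, 0.07087482, -0.02426757, 0.996843243],
    ]
)

#: August radon-flux risk thresholds (kBq m^-2 s^-1): 25th percentile, mean
#: and median of the 2006-2021 August measurements
RISK_THRESHOLDS = (19.326, 22.75, 23.994)

_PARAMS = (
    # (k1, k2, k3, spatial range km, temporal range months)
    (0.0047, 0.0358, 0.0081, 20.0, 2.0),
    (15.0756, 10.6321, 33.4605, 30.0, 3.0),
    (15.1367, 30.703, 0.01, 55.0, 7.0),
    (0.01, 17.0644, 2.9732, 120.0, 12.0),
)

_B = (
    np.array(
        [
            [663.8366, 86.7824, -121.4861, 8.5663],
            [86.7824, 109.8702, -89.6217, 9.3176],
            [-121.4861, -89.6217, 1214.1283, -21.6994],
            [8.5663, 9.3176, -21.6994, 1.8972],
        ]
    ),
    np.array(
        [
            [0.1100, 0.0236, -0.0443, 0.0029],
            [0.0236, 0.0380, 0.0057, 0.0037],
            [-0.0443, 0.0057, 0.0601, -0.0005],
            [0.0029, 0.0037, -0.0005, 0.0004],
        ]
    ),
    np.array(
        [
            [0.2043, 0.0537, -0.0640, 0.0012],
            [0.0537, 0.0485, 0.0156, 0.0029],
            [-0.0640, 0.0156, 0.0520, 0.0020],
            [0.0012, 0.0029, 0.0020, 0.0040],
        ]
    ),
    np.array(
        [
            [0.4020, -0.2880, -0.1704, -0.0200],
            [-0.2880, 0.5900, 0.2110, 0.0100],
            [-0.1704, 0.2110, 0.4000, 0.0116],
            [-0.0200, 0.0100, 0.0116, 0.0011],
        ]
    ),
)

_INTRINSIC_B = np.array(
    [
        [2.8031, 0.1150, -0.4013, 0.0122],
        [0.1150, 1.0793, 0.0464, 0.0501],
        [-0.4013, 0.0464, 3.2720, -0.0378],
        [0.0122, 0.0501, -0.0378, 0.0160],
    ]
)


def _component(k1, k2, k3, a, b) -> ProductSumComponent:
    return ProductSumComponent(
        k1=k1, k2=k2, k3=k3,
        spatial=ExponentialMarginal(a), temporal=ExponentialMarginal(b),
    )


def veneto_fitted_model() -> STLCM:
    """The published four-component ST-LCM for the Veneto variables.

    Basic-structure sills c_l(0,0) are 0.0486, 59.1682, 45.8497 and 20.0476
    (scales 20 km/2 mo up to 120 km/12 mo); the radon-flux sill of the
    assembled model is about 56.20 (kBq m^-2 s^-1)^2.
    """
    comps = [_component(*p) for p in _PARAMS]
    return STLCM(VARIABLES, comps, list(_B))


def veneto_intrinsic_model() -> STLCM:
    """The one-component intrinsic contender (largest scale only)."""
    comp = _component(0.010, 17.0644, 2.9732, 120.0, 12.0)
    return STLCM(VARIABLES, [comp], [_INTRINSIC_B])
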