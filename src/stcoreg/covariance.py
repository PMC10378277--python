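"""Space-time covariance models.

The building block is the *product-sum* covariance

    c(hs, ht) = k1 * Cs(hs) * Ct(ht) + k2 * Cs(hs) + k3 * Ct(ht),

where ``Cs`` and ``Ct`` are exponential correlation functions of the spatial
and temporal lag, and the full multivariate model is the space-time linear
coregionalization model (ST-LCM)

    C(h) = sum_l  B_l * c_l(h),

a p x p matrix-valued covariance obtained by weighting L basic structures
``c_l`` with symmetric positive semi-definite coregionalization matrices
``B_l``.  The basic structures are kept in whatever (non-unit) sill scale the
fitting procedure delivers; the ``B_l`` carry the physical units.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ExponentialMarginal",
    "ProductSumComponent",
    "STLag",
    "STLCM",
    "AdmissibilityReport",
    "PSDReport",
    "eval_product_sum",
    "eval_stlcm",
    "check_admissibility",
    "check_psd",
]


@dataclasses.dataclass(frozen=True)
class ExponentialMarginal:
    """Exponential correlation ``exp(-3|h| / a)`` with practical range ``a``.

    The 3/a scaling is the standard geostatistical convention: the correlation
    has decayed to about 5% of its zero-lag value at ``|h| = a``.  The range is
    in km for spatial marginals and months for temporal ones.
    """

    practical_range: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.practical_range) or self.practical_range <= 0:
            raise ValueError(
                f"practical_range must be positive and finite, got {self.practical_range!r}"
            )

    def __call__(self, lag) -> np.ndarray | float:
        lag = np.abs(np.asarray(lag, dtype=float))
        return np.exp(-3.0 * lag / self.practical_range)


@dataclasses.dataclass(frozen=True)
class ProductSumComponent:
    """One basic structure of an ST-LCM: a product-sum covariance.

    ``k1`` weights the space-time interaction term, ``k2`` the purely spatial
    term and ``k3`` the purely temporal term; all are dimensionless and the
    sill at the origin is ``k1 + k2 + k3``.  Strict positive definiteness
    requires ``k1 > 0`` with ``k2, k3 >= 0``.
    """

    k1: float
    k2: float
    k3: float
    spatial: ExponentialMarginal
    temporal: ExponentialMarginal

    @property
    def sill(self) -> float:
        return self.k1 + self.k2 + self.k3

    @property
    def spatial_range(self) -> float:
        return self.spatial.practical_range

    @property
    def temporal_range(self) -> float:
        return self.temporal.practical_range

    def __call__(self, hs_norm, ht):
        hs_norm = np.asarray(hs_norm, dtype=float)
        if np.any(hs_norm < 0):
            raise ValueError("spatial lag norm must be non-negative")
        cs = self.spatial(hs_norm)
        ct = self.temporal(ht)
        return self.k1 * cs * ct + self.k2 * cs + self.k3 * ct


def eval_product_sum(comp: ProductSumComponent, hs_norm, ht):
    """Evaluate a product-sum basic structure at spatial/temporal lag."""
    return comp(hs_norm, ht)


@dataclasses.dataclass(frozen=True)
class STLag:
    """A space-time separation: spatial vector (km) and temporal lag (months)."""

    hs: tuple[float, ...] | float
    ht: float

    @property
    def hs_norm(self) -> float:
        hs = np.atleast_1d(np.asarray(self.hs, dtype=float))
        return float(np.linalg.norm(hs))


@dataclasses.dataclass(frozen=True)
class AdmissibilityReport:
    passed: bool
    strictly_positive_definite: bool
    positive_semi_definite: bool
    reasons: tuple[str, ...]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def check_admissibility(comp: ProductSumComponent) -> AdmissibilityReport:
    """Check that a product-sum component is a valid (strictly PD) covariance.

    Returns structured reasons instead of raising, so callers can report which
    constraint failed.  ``k1 = 0`` with non-negative ``k2, k3`` is flagged as
    only positive semi-definite.
    """
    reasons: list[str] = []
    if comp.k1 < 0:
        reasons.append(f"k1 must be non-negative, got {comp.k1}")
    if comp.k2 < 0:
        reasons.append(f"k2 must be non-negative, got {comp.k2}")
    if comp.k3 < 0:
        reasons.append(f"k3 must be non-negative, got {comp.k3}")
    # ranges are validated at construction, but re-check defensively
    for name, rng in (("spatial", comp.spatial_range), ("temporal", comp.temporal_range)):
        if not np.isfinite(rng) or rng <= 0:
            reasons.append(f"{name} practical range must be positive, got {rng}")
    semi = not reasons
    strict = semi and comp.k1 > 0
    if semi and not strict:
        reasons.append("k1 = 0: component is positive semi-definite but not strictly PD")
    return AdmissibilityReport(
        passed=strict,
        strictly_positive_definite=strict,
        positive_semi_definite=semi,
        reasons=tuple(reasons),
    )


@dataclasses.dataclass(frozen=True)
class PSDReport:
    passed: bool
    min_eigenvalue: float

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def check_psd(
    matrix: np.ndarray, tol_psd: float = 1e-10, sym_tol: float = 1e-8
) -> PSDReport:
    """Check symmetry and positive semi-definiteness of a square matrix.

    ``tol_psd`` is relative to the largest absolute eigenvalue (eigenvalues
    above ``-tol_psd * scale`` count as non-negative).  A matrix that is not
    symmetric within ``sym_tol`` (relative) raises ``ValueError``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    scale = max(float(np.abs(m).max()), 1.0)
    if np.abs(m - m.T).max() > sym_tol * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    eig = np.linalg.eigvalsh((m + m.T) / 2.0)
    min_eig = float(eig.min())
    eig_scale = max(float(np.abs(eig).max()), 1.0)
    return PSDReport(passed=min_eig >= -tol_psd * eig_scale, min_eigenvalue=min_eig)


class STLCM:
    """Space-time linear coregionalization model over named variables.

    Parameters
    ----------
    variables:
        Ordered names of the p coregionalized variables.
    components:
        The L basic product-sum structures.
    coreg:
        The L symmetric positive semi-definite p x p coregionalization
        matrices, in the same order as ``components``.
    """

    def __init__(
        self,
        variables: Sequence[str],
        components: Sequence[ProductSumComponent],
        coreg: Sequence[np.ndarray],
        *,
        tol_psd: float = 1e-10,
    ) -> None:
        self.variables = tuple(str(v) for v in variables)
        self.components = list(components)
        self.coreg = [np.array(b, dtype=float, copy=True) for b in coreg]
        p = len(self.variables)
        if len(set(self.variables)) != p:
            raise ValueError("variable names must be unique")
        if len(self.components) != len(self.coreg):
            raise ValueError(
                f"{len(self.components)} components but {len(self.coreg)} coregionalization matrices"
            )
        if not self.components:
            raise ValueError("an ST-LCM needs at least one basic component")
        # note: component *selection* keeps L <= p (enforced at assembly);
        # restrictions of a larger model to fewer variables may carry L > p
        for l, b in enumerate(self.coreg):
            if b.shape != (p, p):
                raise ValueError(f"B_{l + 1} has shape {b.shape}, expected {(p, p)}")
            report = check_psd(b, tol_psd=tol_psd)
            if not report.passed:
                raise ValueError(
                    f"B_{l + 1} is not positive semi-definite "
                    f"(min eigenvalue {report.min_eigenvalue:.3e})"
                )
            # enforce exact symmetry after the tolerance check
            self.coreg[l] = (b + b.T) / 2.0

    # -- basic introspection ------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def L(self) -> int:
        return len(self.components)

    def index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"unknown variable {variable!r}; model has {self.variables}")

    # -- evaluation ---------------------------------------------------------
    def cov(self, i: int, j: int, hs_norm, ht):
        """Direct (i == j) or cross (i != j) covariance at the given lag."""
        p = self.p
        if not (0 <= i < p and 0 <= j < p):
            raise IndexError(f"variable indices ({i}, {j}) out of range for p={p}")
        hs_norm = np.asarray(hs_norm, dtype=float)
        out = np.zeros(np.broadcast(hs_norm, np.asarray(ht, float)).shape)
        for b, comp in zip(self.coreg, self.components):
            out = out + b[i, j] * comp(hs_norm, ht)
        return out if out.shape else float(out)

    def cov_matrix(self, hs_norm: float, ht: float) -> np.ndarray:
        """The full p x p covariance matrix at one space-time lag."""
        out = np.zeros((self.p, self.p))
        for b, comp in zip(self.coreg, self.components):
            out += b * float(comp(hs_norm, ht))
        return out

    def sill_matrix(self) -> np.ndarray:
        return self.cov_matrix(0.0, 0.0)

    def select(self, variables: Sequence[str]) -> "STLCM":
        """Sub-model restricted to a subset of variables.

        All basic components are kept (with the corresponding blocks of the
        coregionalization matrices), so the restriction evaluates to exactly
        the same direct/cross covariances as the full model.
        """
        idx = [self.index(v) for v in variables]
        coreg = [b[np.ix_(idx, idx)] for b in self.coreg]
        return STLCM([self.variables[k] for k in idx], list(self.components), coreg)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "components": [
                {
                    "k1": c.k1,
                    "k2": c.k2,
                    "k3": c.k3,
                    "spatial_range_km": c.spatial_range,
                    "temporal_range_months": c.temporal_range,
                }
                for c in self.components
            ],
            "coreg": [b.ravel().tolist() for b in self.coreg],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "STLCM":
        variables = d["variables"]
        p = len(variables)
        comps = [
            ProductSumComponent(
                k1=float(c["k1"]),
                k2=float(c["k2"]),
                k3=float(c["k3"]),
                spatial=ExponentialMarginal(float(c["spatial_range_km"])),
                temporal=ExponentialMarginal(float(c["temporal_range_months"])),
            )
            for c in d["components"]
        ]
        coreg = [np.asarray(b, dtype=float).reshape(p, p) for b in d["coreg"]]
        return cls(variables, comps, coreg)

    def save(self, path) -> None:
        """Write the model to a YAML (.yaml/.yml) or JSON (.json) file."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def load(cls, path) -> "STLCM":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        scales = ", ".join(
            f"({c.spatial_range:g} km, {c.temporal_range:g} mo)" for c in self.components
        )
        return f"STLCM(p={self.p}, L={self.L}, scales=[{scales}])"


def eval_stlcm(model: STLCM, i: int, j: int, lag: STLag):
    """Evaluate the matrix-valued ST-LCM entry ``C_ij`` at a space-time lag."""
    return model.cov(i, j, lag.hs_norm, lag.ht)
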