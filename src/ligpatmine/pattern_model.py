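"""Gaussian-mixture interaction patterns and pattern assignment.

For each (protein-fragment type, ligand-atom type) combination, the local
coordinates of all observed contacts form a 3D point cloud.  A Gaussian
mixture is fitted to each cloud by expectation–maximisation with full
covariances; the number of components K is chosen by the Bayesian
information criterion over K = 1..k_max with several seeded restarts each.
Every fitted Gaussian component is one *interaction pattern*: a
statistically preferred position of that ligand-atom type relative to that
fragment.

A contact is assigned to a pattern when its Mahalanobis distance to the
component, sqrt((x−μ)ᵀ Σ⁻¹ (x−μ)), is at most a threshold (default 2.5);
several patterns may be assigned simultaneously.  The mixture density
Σ_k w_k N(x; μ_k, Σ_k) at the contact quantifies how typical the observed
geometry is.

Numerical choices: covariances get a small diagonal floor (1e-4 Å²) so EM
cannot collapse onto single points; Mahalanobis distances and component
densities are computed through Cholesky factorisations, never explicit
inverses; the per-iteration log-likelihood is asserted non-decreasing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp

from .config import ENGINE_VERSION, FRAME_CONVENTION, LIBRARY_SCHEMA_VERSION

_LOG_2PI = math.log(2.0 * math.pi)


class LibraryIntegrityError(ValueError):
    """A pattern library violates its invariants (weights, SPD covariances, ...)."""


@dataclass
class GaussianComponent:
    """One interaction pattern: a single 3D Gaussian."""

    pattern_id: int
    weight: float
    mean: np.ndarray            # (3,), Å
    covariance: np.ndarray      # (3,3), Å², symmetric positive definite
    support_count: int = 0      # contacts assigned at mining time
    family_count: int = 0       # distinct protein families among supporters

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(3)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(3, 3)
        if not (0.0 < self.weight <= 1.0 + 1e-12):
            raise LibraryIntegrityError(f"component weight {self.weight} outside (0,1]")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-9):
            raise LibraryIntegrityError("covariance not symmetric")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() <= 1e-6:
            raise LibraryIntegrityError(
                f"covariance eigenvalue {eig.min():.2e} ≤ 1e-6 Å²")

    def _chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.covariance)


@dataclass
class MixtureModel:
    """The interaction-pattern set of one combination."""

    combination: tuple[str, str]        # (fragment type label, ligand atom type)
    components: list[GaussianComponent]
    n_points: int
    frame_convention: str = FRAME_CONVENTION

    def __post_init__(self):
        total = sum(c.weight for c in self.components)
        if self.components and abs(total - 1.0) > 1e-9:
            raise LibraryIntegrityError(
                f"{self.combination}: weights sum to {total}, expected 1")

    @property
    def k(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class PatternAssignment:
    pattern_id: int
    mahalanobis: float
    mixture_density: float  # Å⁻³, full mixture density at the point


# ---------------------------------------------------------------------------
# EM fitting

def _log_gauss(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x; mean, cov) for each row of points, via Cholesky."""
    chol = np.linalg.cholesky(cov)
    dev = solve_triangular(chol, (points - mean).T, lower=True)
    maha2 = np.sum(dev * dev, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (points.shape[1] * _LOG_2PI + logdet + maha2)


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding of component means."""
    n = len(points)
    means = [points[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min([np.sum((points - m) ** 2, axis=1) for m in means], axis=0)
        total = d2.sum()
        if total <= 0:
            means.append(points[rng.integers(n)])
        else:
            means.append(points[rng.choice(n, p=d2 / total)])
    return np.array(means)


def _em_once(points: np.ndarray, k: int, rng: np.random.Generator,
             covariance_floor: float, max_iter: int = 300,
             tol: float = 1e-7) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One EM run; returns (weights, means, covariances, total log-likelihood).

    The mean log-likelihood is asserted non-decreasing every iteration — a
    violated assertion indicates a bug, not bad data.  With a covariance
    floor the M-step is not the exact maximiser (the floor is re-added to
    the diagonals afterwards), so the assertion carries a slack of the same
    order as the floor; it is exact as the floor goes to zero.
    """
    n, d = points.shape
    ll_slack = 1e-9 + 10.0 * covariance_floor
    floor = covariance_floor * np.eye(d)
    means = _kmeanspp_init(points, k, rng)
    base_cov = np.cov(points.T) if n > 1 else np.eye(d)
    base_cov = np.atleast_2d(base_cov) + floor
    covs = np.array([base_cov.copy() for _ in range(k)])
    weights = np.full(k, 1.0 / k)

    prev_ll = -np.inf
    for _it in range(max_iter):
        log_prob = np.column_stack([
            np.log(weights[j]) + _log_gauss(points, means[j], covs[j])
            for j in range(k)
        ])
        log_norm = logsumexp(log_prob, axis=1)
        ll = float(log_norm.mean())
        assert ll >= prev_ll - ll_slack, \
            f"EM log-likelihood decreased: {prev_ll} -> {ll}"
        resp = np.exp(log_prob - log_norm[:, None])

        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ points) / nk[:, None]
        for j in range(k):
            dev = points - means[j]
            covs[j] = (resp[:, j][:, None] * dev).T @ dev / nk[j] + floor
        if ll - prev_ll < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return weights, means, covs, prev_ll * n


def _bic(ll_total: float, k: int, n: int, d: int = 3) -> float:
    n_params = (k - 1) + k * d + k * d * (d + 1) // 2
    return -2.0 * ll_total + n_params * math.log(n)


def fit_mixture(points: np.ndarray, combination: tuple[str, str] = ("", ""),
                k_max: int = 10, n_restarts: int = 5, seed: int = 0,
                min_points: int = 20,
                covariance_floor: float = 1e-4) -> MixtureModel | None:
    """Fit a Gaussian mixture to a 3D point cloud, selecting K by BIC.

    Returns None (the combination gets no patterns) when fewer than
    ``min_points`` points are available.  Deterministic for a fixed seed.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = len(points)
    if n < min_points:
        return None
    if k_max < 1:
        raise ValueError("k_max must be ≥ 1")

    rng = np.random.default_rng(seed)
    best = None
    best_bic = np.inf
    for k in range(1, min(k_max, n) + 1):
        for _restart in range(n_restarts):
            try:
                w, mu, cov, ll = _em_once(points, k, rng, covariance_floor)
            except np.linalg.LinAlgError:
                continue
            if np.any(w * n < 1.0):  # starved component: unsupported pattern
                continue
            bic = _bic(ll, k, n)
            if bic < best_bic:
                best_bic = bic
                best = (w, mu, cov)
    if best is None:  # every K>1 starved: refit plain K=1 (cannot starve)
        w, mu, cov, _ll = _em_once(points, 1, rng, covariance_floor)
        best = (w, mu, cov)

    w, mu, cov = best
    w = w / w.sum()
    comps = [
        GaussianComponent(pattern_id=-1, weight=float(w[j]), mean=mu[j],
                          covariance=cov[j])
        for j in range(len(w))
    ]
    return MixtureModel(combination=combination, components=comps, n_points=n)


# ---------------------------------------------------------------------------
# assignment and density

def mahalanobis_distance(point: np.ndarray, component: GaussianComponent) -> float:
    """sqrt((x−μ)ᵀ Σ⁻¹ (x−μ)) via a Cholesky factorisation of Σ."""
    dev = np.asarray(point, dtype=float) - component.mean
    try:
        factor = cho_factor(component.covariance, lower=True)
    except np.linalg.LinAlgError as exc:
        raise LibraryIntegrityError("covariance not positive definite") from exc
    return float(math.sqrt(dev @ cho_solve(factor, dev)))


def mixture_density(point: np.ndarray, model: MixtureModel) -> float:
    """Full mixture density Σ_k w_k N(x; μ_k, Σ_k) at the point, Å⁻³."""
    point = np.asarray(point, dtype=float).reshape(1, 3)
    log_terms = [
        math.log(c.weight) + float(_log_gauss(point, c.mean, c.covariance)[0])
        for c in model.components
    ]
    if not log_terms:
        return 0.0
    return float(np.exp(logsumexp(log_terms)))


def assign_patterns(point: np.ndarray, model: MixtureModel,
                    threshold: float = 2.5) -> list[PatternAssignment]:
    """All components within the Mahalanobis threshold, nearest first."""
    density = None
    out = []
    for comp in model.components:
        d = mahalanobis_distance(point, comp)
        if d <= threshold:
            if density is None:
                density = mixture_density(point, model)
            out.append(PatternAssignment(pattern_id=comp.pattern_id,
                                         mahalanobis=d, mixture_density=density))
    out.sort(key=lambda a: (a.mahalanobis, a.pattern_id))
    return out


# ---------------------------------------------------------------------------
# pattern library

@dataclass
class PatternLibrary:
    """All mixtures mined from one dataset, plus the mining conditions."""

    models: dict[tuple[str, str], MixtureModel] = field(default_factory=dict)
    frame_convention: str = FRAME_CONVENTION
    offset: float = 1.0
    mahalanobis_threshold: float = 2.5
    radius_table: dict[str, float] = field(default_factory=dict)
    default_radius: float = 1.7
    schema_version: str = LIBRARY_SCHEMA_VERSION
    engine_version: str = ENGINE_VERSION

    def n_patterns(self) -> int:
        return sum(m.k for m in self.models.values())

    def components(self):
        for model in self.models.values():
            for comp in model.components:
                yield model, comp

    def assign_ids(self) -> None:
        """Sequential pattern ids over combinations in sorted order."""
        next_id = 1
        for key in sorted(self.models):
            for comp in self.models[key].components:
                comp.pattern_id = next_id
                next_id += 1

    def lookup(self, fragment_type: str, ligand_type: str) -> MixtureModel | None:
        return self.models.get((fragment_type, ligand_type))

    def component_by_id(self, pattern_id: int) -> tuple[MixtureModel, GaussianComponent]:
        for model, comp in self.components():
            if comp.pattern_id == pattern_id:
                return model, comp
        raise KeyError(f"no pattern with id {pattern_id}")

    def validate(self) -> None:
        seen: set[int] = set()
        for model, comp in self.components():
            if comp.pattern_id in seen:
                raise LibraryIntegrityError(f"duplicate pattern id {comp.pattern_id}")
            seen.add(comp.pattern_id)
            if model.frame_convention != self.frame_convention:
                raise LibraryIntegrityError("mixed frame conventions in library")


def save_library(library: PatternLibrary, path) -> None:
    library.validate()
    doc = {
        "schema_version": library.schema_version,
        "engine_version": library.engine_version,
        "frame_convention": library.frame_convention,
        "offset": library.offset,
        "mahalanobis_threshold": library.mahalanobis_threshold,
        "radius_table": library.radius_table,
        "default_radius": library.default_radius,
        "combinations": [
            {
                "fragment_type": key[0],
                "ligand_type": key[1],
                "n_points": model.n_points,
                "components": [
                    {
                        "pattern_id": c.pattern_id,
                        "weight": c.weight,
                        "mean": c.mean.tolist(),
                        "covariance": c.covariance.tolist(),
                        "support_count": c.support_count,
                        "family_count": c.family_count,
                    }
                    for c in model.components
                ],
            }
            for key, model in sorted(library.models.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_library(path) -> PatternLibrary:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        models: dict[tuple[str, str], MixtureModel] = {}
        for entry in doc["combinations"]:
            key = (entry["fragment_type"], entry["ligand_type"])
            comps = [
                GaussianComponent(
                    pattern_id=int(c["pattern_id"]),
                    weight=float(c["weight"]),
                    mean=np.array(c["mean"], dtype=float),
                    covariance=np.array(c["covariance"], dtype=float),
                    support_count=int(c.get("support_count", 0)),
                    family_count=int(c.get("family_count", 0)),
                )
                for c in entry["components"]
            ]
            models[key] = MixtureModel(
                combination=key, components=comps,
                n_points=int(entry["n_points"]),
                frame_convention=doc["frame_convention"],
            )
        library = PatternLibrary(
            models=models,
            frame_convention=doc["frame_convention"],
            offset=float(doc["offset"]),
            mahalanobis_threshold=float(doc["mahalanobis_threshold"]),
            radius_table={k: float(v) for k, v in doc.get("radius_table", {}).items()},
            default_radius=float(doc.get("default_radius", 1.7)),
            schema_version=str(doc.get("schema_version", "?")),
            engine_version=str(doc.get("engine_version", "?")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, LibraryIntegrityError):
            raise
        raise LibraryIntegrityError(f"malformed pattern library {path}: {exc}") from exc
    library.validate()
    return library
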