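"""Reaction-diffusion patterning on a two-zone petal domain.

The petal is a rectangular grid split into a proximal *nectar guide* zone
(ancestrally spotted in Mimulus luteus) and a distal *lobe* zone.  The two
zones share all kinetics except the basal activator production ``sigma_a``:
genotypes differ in how strongly each zone drives MYB5a expression, and RNAi
knockdown scales total activator production everywhere by ``f < 1``.

Pattern regimes along increasing lobe ``sigma_a`` (at the shipped fixture
kinetics):

* low drive — a stable low-activator branch exists and the field stays
  unpigmented (``uniform_low``; the yellow M. l. luteus lobe);
* intermediate drive — only the high branch exists and it is Turing
  unstable, so noise breaks the field into anthocyanin spots (``spotted``;
  the hybrid/F1 lobe and the luteus nectar guide);
* high drive — saturation stabilizes the high branch and pigment fills the
  zone (``uniform_high``; the solid purple M. l. variegatus lobe).

Decreasing ``f`` walks the same path in reverse, ending in complete pigment
loss, which is the strong-RNAi phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .rd_core import (
    I_EPSILON,
    NetworkParams,
    steady_state,
    steady_state_branches,
)

__all__ = [
    "NECTAR_GUIDE",
    "LOBE",
    "DomainLayout",
    "GenotypePreset",
    "GridField",
    "ThresholdRule",
    "PatternSummary",
    "default_presets",
    "stability_dt_bound",
    "integrate_rd",
    "summarize_pattern",
    "genotype_series",
]

NECTAR_GUIDE = "nectar_guide"
LOBE = "lobe"

GENOTYPE_ORDER = ("luteus", "variegatus", "F1", "rnai_strong", "rnai_partial")


def default_params() -> NetworkParams:
    """The shipped petal-patterning kinetics.

    Chosen so that sweeping the basal drive ``sigma_a`` traverses the three
    phenotype regimes (bistable-low below ~0.01, Turing-spotted around
    0.05-0.1, saturated-high above ~0.2) while the inhibitor's long range
    (D_i/D_a = 50) keeps spot fronts pinned at zone boundaries.
    """
    return NetworkParams(
        sigma_a=0.05, sigma_i=0.2, rho_a=1.0, rho_i=1.0, mu_a=1.0, mu_i=1.5,
        kappa=0.2, n_coop=2.0, D_a=0.25, D_i=12.5, f_knockdown=1.0,
    )


@dataclass(frozen=True)
class DomainLayout:
    """Rectangular petal grid with a per-cell zone label and no-flux edges.

    ``zone_mask`` holds the strings ``"nectar_guide"`` / ``"lobe"``; both
    zones must be non-empty.  ``h`` is the cell edge length.
    """

    shape: tuple[int, int]
    h: float
    zone_mask: np.ndarray
    boundary: str = "no_flux"

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"grid spacing h must be > 0, got {self.h}")
        if self.boundary != "no_flux":
            raise ValueError("only no-flux boundaries are supported")
        if tuple(self.zone_mask.shape) != tuple(self.shape):
            raise ValueError("zone_mask shape does not match domain shape")
        for zone in (NECTAR_GUIDE, LOBE):
            if not np.any(self.zone_mask == zone):
                raise ValueError(f"zone {zone!r} is empty")

    @classmethod
    def default(cls, rows: int = 96, cols: int = 64, h: float = 1.0,
                guide_fraction: float = 1 / 3) -> "DomainLayout":
        """Petal with the proximal ``guide_fraction`` of rows as nectar guide."""
        n_guide = max(1, int(round(rows * guide_fraction)))
        mask = np.full((rows, cols), LOBE, dtype="<U12")
        mask[:n_guide, :] = NECTAR_GUIDE
        return cls(shape=(rows, cols), h=h, zone_mask=mask)

    def zone_indices(self, zone: str) -> np.ndarray:
        return self.zone_mask == zone


@dataclass(frozen=True)
class GenotypePreset:
    """Per-zone basal activator drive and global knockdown for one genotype."""

    name: str
    sigma_a_by_zone: dict
    f_knockdown: float = 1.0

    def __post_init__(self) -> None:
        missing = {NECTAR_GUIDE, LOBE} - set(self.sigma_a_by_zone)
        if missing:
            raise ValueError(f"preset {self.name!r} missing zones: {sorted(missing)}")
        if any(v < 0 for v in self.sigma_a_by_zone.values()):
            raise ValueError("sigma_a values must be >= 0")
        if not (0 < self.f_knockdown <= 1):
            raise ValueError("f_knockdown must lie in (0, 1]")


def default_presets() -> dict[str, GenotypePreset]:
    """The shipped genotype series.

    luteus: unpigmented (yellow) lobe, spotted nectar guide.
    variegatus: solid pigmented lobe.  F1: intermediate lobe drive, spots.
    rnai presets knock down activator production in the variegatus
    background; the strong line loses pigment in both zones, the partial
    line retains scattered spotting.
    """
    guide = 0.10
    return {
        "luteus": GenotypePreset("luteus", {NECTAR_GUIDE: guide, LOBE: 0.002}),
        "variegatus": GenotypePreset("variegatus", {NECTAR_GUIDE: guide, LOBE: 0.30}),
        "F1": GenotypePreset("F1", {NECTAR_GUIDE: guide, LOBE: 0.05}),
        "rnai_strong": GenotypePreset(
            "rnai_strong", {NECTAR_GUIDE: guide, LOBE: 0.30}, f_knockdown=0.05),
        "rnai_partial": GenotypePreset(
            "rnai_partial", {NECTAR_GUIDE: guide, LOBE: 0.30}, f_knockdown=0.45),
    }


@dataclass
class GridField:
    """Activator/inhibitor concentration fields at time ``t`` (non-negative)."""

    a_field: np.ndarray
    i_field: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.a_field.shape != self.i_field.shape:
            raise ValueError("a_field and i_field shapes differ")


def stability_dt_bound(params: NetworkParams, h: float) -> float:
    """Largest time step the explicit scheme tolerates: h^2 / (4 max D)."""
    d_max = max(params.D_a, params.D_i)
    return math.inf if d_max == 0 else h * h / (4.0 * d_max)


def _laplacian(u: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with reflecting (no-flux) edges."""
    up = np.pad(u, 1, mode="edge")
    return (up[:-2, 1:-1] + up[2:, 1:-1] + up[1:-1, :-2] + up[1:-1, 2:] - 4.0 * u) / (h * h)


def _init_level(params: NetworkParams, mode: str) -> tuple[float, float]:
    """Homogeneous initial (a, i) for one zone's parameters."""
    if mode == "steady":
        ss = steady_state(params)
        if ss.trivial:
            return 0.01, params.sigma_i / params.mu_i
        return ss.a, ss.i
    if mode == "low":
        branches = [b for b in steady_state_branches(params) if b.stable]
        if branches:
            return branches[0].a, branches[0].i
        return 0.01, params.sigma_i / params.mu_i
    raise ValueError(f"unknown init mode {mode!r}")


def integrate_rd(
    params: NetworkParams,
    layout: DomainLayout,
    preset: GenotypePreset | None = None,
    t_end: float = 150.0,
    dt: float | None = None,
    noise_amplitude: float = 0.01,
    seed: int = 0,
    init: str = "low",
) -> GridField:
    """Explicit forward-Euler reaction-diffusion integration on the petal.

    ``preset`` overrides ``sigma_a`` per zone and the global knockdown
    factor; without one the params apply uniformly.  The field starts at the
    per-zone homogeneous state selected by ``init`` ("low": lowest stable
    branch, the unpigmented ground state pigment develops from; "steady":
    the high/pigmented branch) plus seeded uniform noise of relative
    amplitude ``noise_amplitude``.

    ``dt`` defaults to half the explicit stability bound
    ``h^2 / (4 max(D_a, D_i))``; a caller-supplied ``dt`` above the bound is
    rejected with the bound in the message.
    """
    p = params if preset is None else params.with_(f_knockdown=preset.f_knockdown)
    bound = stability_dt_bound(p, layout.h)
    if dt is None:
        dt = 0.5 * bound if math.isfinite(bound) else t_end / 1000.0
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt > bound:
        raise ValueError(
            f"dt={dt} violates the explicit-scheme stability bound "
            f"h^2/(4*max(D_a,D_i)) = {bound:.6g}"
        )

    rows, cols = layout.shape
    sigma_map = np.full((rows, cols), p.sigma_a)
    a0 = np.empty((rows, cols))
    i0 = np.empty((rows, cols))
    zones = [NECTAR_GUIDE, LOBE]
    for zone in zones:
        idx = layout.zone_indices(zone)
        zone_sigma = preset.sigma_a_by_zone[zone] if preset is not None else p.sigma_a
        sigma_map[idx] = zone_sigma
        za, zi = _init_level(p.with_(sigma_a=zone_sigma), init)
        a0[idx], i0[idx] = za, zi

    rng = np.random.default_rng(seed)
    if noise_amplitude > 0:
        scale_a = max(float(a0.mean()), 1e-3)
        scale_i = max(float(i0.mean()), 1e-3)
        a0 = a0 + noise_amplitude * scale_a * rng.uniform(-1, 1, size=a0.shape)
        i0 = i0 + noise_amplitude * scale_i * rng.uniform(-1, 1, size=i0.shape)
    a = np.maximum(a0, 0.0)
    i = np.maximum(i0, 0.0)

    f, n = p.f_knockdown, p.n_coop
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        auto = p.rho_a * a * a / ((1.0 + p.kappa * a * a) * np.maximum(i, I_EPSILON))
        da = f * (sigma_map + auto) - p.mu_a * a + p.D_a * _laplacian(a, layout.h)
        di = p.sigma_i + p.rho_i * np.power(a, n) - p.mu_i * i + p.D_i * _laplacian(i, layout.h)
        a = np.maximum(a + dt * da, 0.0)
        i = np.maximum(i + dt * di, 0.0)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(i))):
            raise RuntimeError(
                f"non-finite field during integration (dt={dt}); reaction stiffness "
                f"requires a smaller step than the diffusion bound {bound:.6g}"
            )
    return GridField(a_field=a, i_field=i, t=n_steps * dt)


@dataclass(frozen=True)
class ThresholdRule:
    """How concentration fields are turned into phenotype calls.

    ``pigment_threshold``: cells with activator at or above it count as
    pigmented; by default the midpoint of (min, max) over the whole domain,
    unless the field is near-constant, in which case ``level_threshold`` is
    used directly.  ``cv_uniform``: zones with spatial coefficient of
    variation below it are uniform (low when the zone mean is below
    ``level_threshold``, else high); otherwise spotted.
    """

    cv_uniform: float = 0.05
    level_threshold: float = 0.5
    pigment_threshold: float | None = None
    near_constant_rel: float = 1e-6

    def resolve_threshold(self, a_field: np.ndarray) -> float:
        if self.pigment_threshold is not None:
            return self.pigment_threshold
        lo, hi = float(a_field.min()), float(a_field.max())
        if hi - lo <= self.near_constant_rel * max(abs(hi), 1e-300):
            return self.level_threshold
        # floor the midpoint at the absolute pigmentation level so a field
        # that is low everywhere is not split at its own noise scale
        return max(0.5 * (lo + hi), self.level_threshold)


@dataclass
class PatternSummary:
    """Quantitative phenotype of one zone (or the whole domain)."""

    classification: str
    pigmented_area_fraction: float
    spot_count: int
    mean_spot_spacing: float | None
    spatial_CV: float


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _summarize_region(a: np.ndarray, mask: np.ndarray, h: float,
                      rule: ThresholdRule, threshold: float) -> PatternSummary:
    vals = a[mask]
    mean = float(vals.mean())
    cv = 0.0 if mean == 0 else float(vals.std() / mean)
    pigmented = (a >= threshold) & mask
    area_fraction = float(pigmented.sum() / mask.sum())

    if area_fraction == 0.0:
        classification = "uniform_low"
    elif cv < rule.cv_uniform:
        classification = "uniform_high" if mean >= rule.level_threshold else "uniform_low"
    else:
        classification = "spotted"

    spot_count = 0
    spacing = None
    if classification == "spotted":
        labels, spot_count = ndimage.label(pigmented, structure=_FOUR_CONN)
        if spot_count >= 2:
            centroids = np.array(ndimage.center_of_mass(pigmented, labels,
                                                        range(1, spot_count + 1)))
            diff = centroids[:, None, :] - centroids[None, :, :]
            dist = np.sqrt((diff ** 2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            spacing = float(dist.min(axis=1).mean() * h)
        if spot_count == 0:  # spotted by CV but nothing supra-threshold in zone
            classification = "uniform_low" if mean < rule.level_threshold else "uniform_high"
    return PatternSummary(
        classification=classification,
        pigmented_area_fraction=area_fraction,
        spot_count=int(spot_count),
        mean_spot_spacing=spacing,
        spatial_CV=cv,
    )


def summarize_pattern(
    field: GridField,
    layout: DomainLayout,
    threshold_rule: ThresholdRule | None = None,
) -> dict[str, PatternSummary]:
    """Phenotype summaries for each zone and the whole domain.

    The pigmentation threshold is resolved once over the whole domain and
    shared by all zones, so per-zone calls are comparable.
    """
    rule = threshold_rule or ThresholdRule()
    a = field.a_field
    if not np.all(np.isfinite(a)):
        raise ValueError("field contains non-finite values")
    threshold = rule.resolve_threshold(a)
    out: dict[str, PatternSummary] = {}
    for zone in (NECTAR_GUIDE, LOBE):
        mask = layout.zone_indices(zone)
        out[zone] = _summarize_region(a, mask, layout.h, rule, threshold)
    out["whole"] = _summarize_region(a, np.ones_like(a, dtype=bool), layout.h, rule, threshold)
    return out


def genotype_series(
    params: NetworkParams,
    layout: DomainLayout,
    presets: dict[str, GenotypePreset] | None = None,
    seed: int = 0,
    t_end: float = 150.0,
    dt: float | None = None,
    noise_amplitude: float = 0.01,
    threshold_rule: ThresholdRule | None = None,
) -> dict[str, dict[str, PatternSummary]]:
    """Simulate and summarize every genotype preset under shared kinetics.

    Returns ``{genotype: {zone: PatternSummary}}`` in a fixed order so runs
    with the same seed and configuration are bit-identical.
    """
    presets = presets or default_presets()
    order = [g for g in GENOTYPE_ORDER if g in presets]
    order += [g for g in presets if g not in order]
    out = {}
    for name in order:
        fld = integrate_rd(params, layout, presets[name], t_end=t_end, dt=dt,
                           noise_amplitude=noise_amplitude, seed=seed)
        out[name] = summarize_pattern(fld, layout, threshold_rule)
    return out
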