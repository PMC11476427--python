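"""Synthetic inputs for the carotid event-risk pipeline.

The real study derives its inputs from MRI (vessel geometry), duplex
ultrasound (velocity landmarks) and an electronic case report form (clinical
covariates).  None of these are publicly available, so this module generates
desk-scale stand-ins:

* planar carotid-bifurcation flow domains (one CCA inlet, ICA/ECA outlets)
  with a smooth cosine-bump stenosis on the ICA branch;
* plaque-bearing vessel cross-sections (lumen, wall ring, fibrous-cap
  plaque as an annular sector);
* ultrasound-like measurement records (PSV, EDV, pulse rate, site areas);
* an imbalanced cohort table with the study's feature schema and a *known*
  logistic ground-truth event model, so that downstream feature-importance
  recovery can be tested against the generative truth.

All generators are deterministic per seed; components draw from independent
substreams of a single master seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "BifurcationGeometry",
    "CrossSectionGeometry",
    "USMeasurement",
    "GenerativeRiskSpec",
    "CohortTable",
    "generate_geometry",
    "generate_cross_section",
    "generate_us_measurement",
    "generate_cohort",
    "substream",
    "IMAGING_FEATURES",
    "SIMULATION_FEATURES",
    "ECRF_FEATURES",
    "ALL_FEATURES",
    "BINARY_FEATURES",
]


def substream(seed: int, tag: str) -> np.random.Generator:
    """Independent child RNG for component ``tag`` of master ``seed``."""
    return np.random.default_rng([int(seed), zlib.adler32(tag.encode())])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


# ---------------------------------------------------------------------------
# flow-domain geometry
# ---------------------------------------------------------------------------


@dataclass
class BifurcationGeometry:
    """Planar carotid-bifurcation channel: straight CCA inlet segment that
    splits at a flow-divider apex into an ICA branch (upper, optionally
    stenosed) and an ECA branch (lower).

    The domain is stored parametrically: each branch is a transfinite blend
    between the straight junction edge and a perpendicular channel of
    half-width ``half_width(name, u)`` around the branch centreline.  The
    boundary polygon is sampled from the same maps, so the polygon and the
    mesh generator always agree.

    Lengths are metres; ``stenosis`` is (severity, centre, length) with
    centre/length as fractions of the ICA branch length.
    """

    widths: dict[str, float]  # reference channel widths (diameters)
    lengths: dict[str, float]
    angles: dict[str, float]  # branch axis angles (rad), ica > 0 > eca
    stenosis: tuple[float, float, float]  # (severity, centre_frac, length_frac)
    seed: int = 0
    transition: float = 0.25  # junction blending zone, fraction of branch length

    # -- junction layout ----------------------------------------------------
    @property
    def x_junction(self) -> float:
        return self.lengths["cca"]

    @property
    def ica_share(self) -> float:
        return self.widths["ica"] / (self.widths["ica"] + self.widths["eca"])

    @property
    def y_apex(self) -> float:
        return self.widths["cca"] / 2 - self.ica_share * self.widths["cca"]

    def _branch_frame(self, name: str):
        w_c = self.widths["cca"]
        if name == "ica":
            share = self.ica_share
            y_lo, y_hi = self.y_apex, w_c / 2
        elif name == "eca":
            share = 1.0 - self.ica_share
            y_lo, y_hi = -w_c / 2, self.y_apex
        else:
            raise KeyError(name)
        a = self.angles[name]
        d = np.array([np.cos(a), np.sin(a)])
        n = np.array([-np.sin(a), np.cos(a)])
        p0 = np.array([self.x_junction, 0.5 * (y_lo + y_hi)])
        half0 = 0.5 * share * w_c  # junction-edge half-height
        return p0, d, n, half0

    def half_width(self, name: str, u) -> np.ndarray:
        """Vertical half-extent of branch ``name`` at axial fraction u.

        Branch blocks use sheared (vertical) cross-sections so they conform
        with the straight junction edge and their walls are monotone graphs
        over x.  Beyond the junction transition the vertical half-extent is
        (w_ref / 2) / cos(angle), i.e. the *perpendicular* channel width
        equals the reference width (times the stenosis factor on the ICA).
        """
        u = np.asarray(u, dtype=float)
        _, _, _, half0 = self._branch_frame(name)
        half_ref = 0.5 * self.widths[name] / np.cos(self.angles[name])
        base = half0 + (half_ref - half0) * _smoothstep(u / self.transition)
        if name == "ica":
            sev, uc, ul = self.stenosis
            if sev > 0:
                inside = np.abs(u - uc) <= ul / 2
                bump = np.where(
                    inside, 0.5 * sev * (1 + np.cos(2 * np.pi * (u - uc) / ul)), 0.0
                )
                base = base * (1.0 - bump)
        return base

    def map_branch(self, name: str, u, t) -> np.ndarray:
        """Sheared block map; u in [0,1] axial, t in [-1,1] transverse.

        Cross-sections are vertical segments centred on the inclined branch
        centreline: at u=0 this is exactly the straight junction sub-edge
        (conforming with the CCA block); beyond the junction transition the
        perpendicular channel width is 2*half_width(u)*cos(angle).
        """
        u = np.asarray(u, dtype=float)
        t = np.asarray(t, dtype=float)
        u, t = np.broadcast_arrays(u, t)
        p0, d, _, _ = self._branch_frame(name)
        L = self.lengths[name]
        h = self.half_width(name, u)
        centre = p0 + (u * L)[..., None] * d
        offset = np.stack([np.zeros_like(t), t * h], axis=-1)
        return centre + offset

    def map_cca(self, s, t) -> np.ndarray:
        """CCA block map; s in [0,1] axial, t in [-1,1] transverse."""
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        s, t = np.broadcast_arrays(s, t)
        return np.stack([s * self.lengths["cca"], t * self.widths["cca"] / 2], axis=-1)

    # -- derived quantities --------------------------------------------------
    @property
    def severity(self) -> float:
        return self.stenosis[0]

    def min_ica_width(self) -> float:
        """Minimal perpendicular ICA lumen width beyond the junction zone."""
        u = np.linspace(self.transition, 1.0, 2001)
        return float(
            2 * self.half_width("ica", u).min() * np.cos(self.angles["ica"])
        )

    def boundary_polygon(self, n_per_seg: int = 60) -> np.ndarray:
        """Closed wall/inlet/outlet boundary polygon (first point repeated last)."""
        u = np.linspace(0, 1, n_per_seg)
        tt = np.linspace(-1, 1, n_per_seg)
        segs = [
            self.map_cca(u, -1.0),                      # CCA bottom wall
            self.map_branch("eca", u, -1.0),            # ECA lower wall
            self.map_branch("eca", 1.0, tt),            # ECA outlet
            self.map_branch("eca", u[::-1], 1.0),       # ECA upper wall -> apex
            self.map_branch("ica", u, -1.0),            # ICA lower wall
            self.map_branch("ica", 1.0, tt),            # ICA outlet
            self.map_branch("ica", u[::-1], 1.0),       # ICA upper wall
            self.map_cca(u[::-1], 1.0),                 # CCA top wall
            self.map_cca(0.0, tt[::-1]),                # inlet edge
        ]
        pts = np.vstack([s.reshape(-1, 2)[:-1] for s in segs])
        return np.vstack([pts, pts[:1]])

    def validate(self) -> None:
        poly = Polygon(self.boundary_polygon()[:-1])
        if not (poly.is_valid and poly.is_simple):
            raise ValueError("boundary polygon is self-intersecting or degenerate")
        sev = self.severity
        target = (1 - sev) * self.widths["ica"]
        if abs(self.min_ica_width() - target) > 0.01 * target:
            raise ValueError("minimal ICA width deviates >1% from (1-s) * reference width")

    # -- serialization -------------------------------------------------------
    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savetxt(
            prefix.with_suffix(".csv"),
            self.boundary_polygon(),
            delimiter=",",
            header="x,y",
            comments="",
        )
        meta = {
            "widths": self.widths,
            "lengths": self.lengths,
            "angles": self.angles,
            "stenosis": list(self.stenosis),
            "seed": self.seed,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def generate_geometry(
    reference_diameters: dict[str, float] | None = None,
    stenosis_severity: float = 0.5,
    seed: int = 0,
) -> BifurcationGeometry:
    """Seed-deterministic synthetic carotid bifurcation.

    ``reference_diameters`` maps 'cca'/'ica'/'eca' to channel widths (m);
    defaults are typical adult carotid calibres.  Branch angles and the
    stenosis centre are drawn from the seed within physiologic ranges, so
    the family of shapes varies across seeds while every length scales
    linearly with the supplied diameters.
    """
    if reference_diameters is None:
        reference_diameters = {"cca": 6e-3, "ica": 5e-3, "eca": 4e-3}
    if any(d <= 0 for d in reference_diameters.values()):
        raise ValueError("diameters must be positive")
    if not 0.0 <= stenosis_severity < 0.95:
        raise ValueError("stenosis severity must lie in [0, 0.95): higher values "
                         "produce a degenerate throat that cannot be meshed")
    rng = substream(seed, "geometry")
    ang_ica = np.deg2rad(rng.uniform(20.0, 30.0))
    ang_eca = -np.deg2rad(rng.uniform(20.0, 30.0))
    centre = rng.uniform(0.5, 0.62)
    geom = BifurcationGeometry(
        widths=dict(reference_diameters),
        lengths={k: 2.5 * v for k, v in reference_diameters.items()},
        angles={"ica": float(ang_ica), "eca": float(ang_eca)},
        stenosis=(float(stenosis_severity), float(centre), 0.3),
        seed=seed,
    )
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# plaque cross-section geometry
# ---------------------------------------------------------------------------


@dataclass
class CrossSectionGeometry:
    """Vessel cross-section at the site of maximum plaque burden.

    Concentric layout: circular lumen of radius ``r_lumen``, wall ring out to
    ``r_outer``, and a fibrous plaque occupying the annular sector between
    radii ``r_plaque_inner``/``r_plaque_outer`` over ``arc_extent`` radians
    centred at ``arc_centre``.  The strip of wall between the lumen and the
    plaque inner radius is the fibrous cap (thickness ``r_plaque_inner -
    r_lumen``).
    """

    r_lumen: float
    r_outer: float
    r_plaque_inner: float
    r_plaque_outer: float
    arc_centre: float  # rad
    arc_extent: float  # rad
    seed: int = 0
    n_arc: int = 256

    def _circle(self, r: float) -> np.ndarray:
        th = np.linspace(0, 2 * np.pi, self.n_arc, endpoint=False)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    @property
    def lumen_contour(self) -> np.ndarray:
        return self._circle(self.r_lumen)

    @property
    def outer_contour(self) -> np.ndarray:
        return self._circle(self.r_outer)

    @property
    def plaque_contours(self) -> list[np.ndarray]:
        if self.arc_extent == 0.0:  # homogeneous (plaque-free) ring
            return []
        th0 = self.arc_centre - self.arc_extent / 2
        th1 = self.arc_centre + self.arc_extent / 2
        th = np.linspace(th0, th1, max(32, self.n_arc // 4))
        inner = np.column_stack(
            [self.r_plaque_inner * np.cos(th), self.r_plaque_inner * np.sin(th)]
        )
        outer = np.column_stack(
            [self.r_plaque_outer * np.cos(th[::-1]), self.r_plaque_outer * np.sin(th[::-1])]
        )
        return [np.vstack([inner, outer])]

    @property
    def cap_thickness(self) -> float:
        return self.r_plaque_inner - self.r_lumen

    def plaque_area_analytic(self) -> float:
        return 0.5 * self.arc_extent * (self.r_plaque_outer**2 - self.r_plaque_inner**2)

    def plaque_area_fraction(self) -> float:
        """Plaque area / wall-ring area; the package's quantitative stand-in
        for 'plaque burden' (no standard closed-form definition exists)."""
        ring = np.pi * (self.r_outer**2 - self.r_lumen**2)
        return self.plaque_area_analytic() / ring

    def validate(self) -> None:
        if not 0 < self.r_lumen < self.r_plaque_inner < self.r_plaque_outer < self.r_outer:
            raise ValueError(
                "contour nesting violated: need lumen < plaque band < outer wall"
            )
        outer = Polygon(self.outer_contour)
        lumen = Polygon(self.lumen_contour)
        for c in [outer, lumen] + [Polygon(p) for p in self.plaque_contours]:
            if not (c.is_valid and c.is_simple):
                raise ValueError("contour is self-intersecting")
        if not outer.contains(lumen):
            raise ValueError("lumen not strictly inside outer wall")
        for p in self.plaque_contours:
            pp = Polygon(p)
            if not outer.contains(pp):
                raise ValueError("plaque contour not inside outer wall")
            if pp.intersects(lumen) and not pp.touches(lumen):
                raise ValueError("plaque contour overlaps the lumen interior")

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for label, contour in [("lumen", self.lumen_contour), ("outer_wall", self.outer_contour)] + [
            (f"plaque_{i}", c) for i, c in enumerate(self.plaque_contours)
        ]:
            for x, y in contour:
                rows.append((label, x, y))
        pd.DataFrame(rows, columns=["region", "x", "y"]).to_csv(path, index=False)


def generate_cross_section(
    wall_thickness: float = 1.5e-3,
    plaque_arc_extent: float = 120.0,
    cap_thickness: float = 0.2e-3,
    seed: int = 0,
    lumen_radius: float = 2.5e-3,
    plaque_thickness: float | None = None,
) -> CrossSectionGeometry:
    """Synthetic plaque-bearing cross-section.

    ``plaque_arc_extent`` is in degrees, in (0, 330]; ``cap_thickness`` is
    the wall strip between lumen and plaque (m).  The plaque radial
    thickness defaults to 60% of the wall thickness remaining beyond the cap.
    """
    if cap_thickness <= 0:
        raise ValueError("cap thickness must be positive")
    if not 0.0 < plaque_arc_extent <= 330.0:
        raise ValueError(
            "plaque arc extent must lie in (0, 330] degrees: the plaque must be "
            "non-degenerate and leave a plaque-free wall sector"
        )
    if plaque_thickness is None:
        plaque_thickness = 0.6 * (wall_thickness - cap_thickness)
    if cap_thickness + plaque_thickness >= wall_thickness:
        raise ValueError("cap + plaque thickness must be smaller than the wall thickness")
    rng = substream(seed, "cross_section")
    geom = CrossSectionGeometry(
        r_lumen=lumen_radius,
        r_outer=lumen_radius + wall_thickness,
        r_plaque_inner=lumen_radius + cap_thickness,
        r_plaque_outer=lumen_radius + cap_thickness + plaque_thickness,
        arc_centre=float(rng.uniform(0, 2 * np.pi)),
        arc_extent=float(np.deg2rad(plaque_arc_extent)),
        seed=seed,
    )
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# ultrasound measurement records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class USMeasurement:
    """Duplex-ultrasound landmarks driving the boundary conditions."""

    psv: float  # m/s
    edv: float  # m/s
    pulse_rate: float  # beats/min
    site_areas: dict[str, float]  # m^2 per measured branch (cca, eca)

    def __post_init__(self):
        if not 0 < self.edv < self.psv:
            raise ValueError("require 0 < EDV < PSV")
        if not 30 <= self.pulse_rate <= 200:
            raise ValueError("pulse rate outside [30, 200] bpm")
        if any(a <= 0 for a in self.site_areas.values()):
            raise ValueError("site areas must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "psv": self.psv, "edv": self.edv, "pulse_rate": self.pulse_rate,
            "site_areas": self.site_areas}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "USMeasurement":
        d = json.loads(Path(path).read_text())
        return cls(d["psv"], d["edv"], d["pulse_rate"], d["site_areas"])


def generate_us_measurement(seed: int = 0, geometry: BifurcationGeometry | None = None) -> USMeasurement:
    """Plausible duplex record; site areas follow the geometry when given."""
    rng = substream(seed, "ultrasound")
    psv = float(rng.uniform(0.6, 1.6))
    edv = float(rng.uniform(0.2, 0.45) * psv)
    pulse = float(rng.uniform(55, 95))
    if geometry is not None:
        areas = {k: np.pi * (geometry.widths[k] / 2) ** 2 for k in ("cca", "eca")}
    else:
        areas = {"cca": np.pi * 3e-3**2, "eca": np.pi * 2e-3**2}
    return USMeasurement(psv, edv, pulse, {k: float(v) for k, v in areas.items()})


# ---------------------------------------------------------------------------
# cohort table with a known generative risk model
# ---------------------------------------------------------------------------

IMAGING_FEATURES = ["artery", "psv", "ica_stenosis_pct", "eca_stenosis_pct",
                    "mean_arterial_pressure"]
SIMULATION_FEATURES = ["peak_tawss", "p_eca_over_cca", "p_ica_over_cca",
                       "vessel_avg_tawss", "vessel_avg_osi",
                       "norm_area_low_tawss", "norm_area_high_osi", "pss"]
ECRF_FEATURES = ["smoking", "diabetes", "hypertension", "bmi", "alcohol_abuse",
                 "statins"]
ALL_FEATURES = IMAGING_FEATURES + SIMULATION_FEATURES + ECRF_FEATURES
BINARY_FEATURES = ["smoking", "diabetes", "hypertension", "alcohol_abuse", "statins"]

# marginal samplers: (kind, params, standardization mean, sd).  Binary
# prevalences follow the study demographics (hypertension 0.83, smoking 0.70,
# diabetes 0.35); continuous ranges are typical of moderate-to-severe carotid
# disease.
_MARGINALS: dict[str, tuple] = {
    "psv": ("normal_clip", (1.4, 0.5, 0.3, 4.0), 1.4, 0.5),
    "ica_stenosis_pct": ("beta_scaled", (5.0, 3.0, 90.0), 56.2, 14.6),
    "eca_stenosis_pct": ("beta_scaled", (2.0, 5.0, 80.0), 22.9, 12.1),
    "mean_arterial_pressure": ("normal_clip", (100.0, 12.0, 60.0, 140.0), 100.0, 12.0),
    "peak_tawss": ("lognormal", (np.log(20.0), 0.5), 22.6, 12.0),
    "p_eca_over_cca": ("normal_clip", (0.97, 0.015, 0.85, 1.0), 0.97, 0.015),
    "p_ica_over_cca": ("normal_clip", (0.92, 0.04, 0.7, 1.0), 0.92, 0.04),
    "vessel_avg_tawss": ("lognormal", (np.log(2.0), 0.4), 2.17, 0.91),
    "vessel_avg_osi": ("beta_scaled", (2.0, 10.0, 0.5), 0.0833, 0.0483),
    "norm_area_low_tawss": ("beta_scaled", (2.0, 6.0, 1.0), 0.25, 0.144),
    "norm_area_high_osi": ("beta_scaled", (2.0, 8.0, 1.0), 0.2, 0.121),
    "pss": ("lognormal", (np.log(60e3), 0.5), 67.9e3, 36.1e3),
    "bmi": ("normal_clip", (26.5, 3.4, 16.0, 45.0), 26.5, 3.4),
    "smoking": ("bernoulli", (0.70,), 0.70, 0.458),
    "diabetes": ("bernoulli", (0.35,), 0.35, 0.477),
    "hypertension": ("bernoulli", (0.83,), 0.83, 0.376),
    "alcohol_abuse": ("bernoulli", (0.10,), 0.10, 0.300),
    "statins": ("bernoulli", (0.60,), 0.60, 0.490),
}

#: Default ground-truth log-odds effects (per SD of each feature) of the
#: generative event model.  Plaque structural stress dominates by design so
#: importance-recovery experiments have a known answer.
DEFAULT_EFFECTS = {
    "pss": 1.5,
    "vessel_avg_tawss": -0.6,
    "vessel_avg_osi": 0.5,
    "norm_area_low_tawss": 0.4,
    "psv": 0.35,
    "ica_stenosis_pct": 0.5,
    "smoking": 0.35,
    "hypertension": 0.4,
    "diabetes": 0.25,
}


def dominant_pss_spec(seed: int = 0, n0: int = 115, n1: int = 19) -> "GenerativeRiskSpec":
    """Risk spec for importance-recovery experiments: the plaque-structural-
    stress effect (2.5 log-odds/SD) dwarfs every other effect (<= 0.6), so
    PSS is the ground-truth top feature by construction."""
    effects = dict(DEFAULT_EFFECTS)
    effects["pss"] = 2.5
    return GenerativeRiskSpec(effects=effects, n0=n0, n1=n1, seed=seed)


@dataclass
class GenerativeRiskSpec:
    """Ground-truth logistic event model for the synthetic cohort.

    ``effects`` are log-odds per standard deviation of each (standardized)
    feature; ``intercept`` is on the logit scale; ``noise_sd`` adds logit
    noise representing unmodelled risk.  ``n0``/``n1`` are the target class
    counts (the study cohort is 115 event-free vs 19 with events).
    """

    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    intercept: float = -2.2
    noise_sd: float = 0.5
    n0: int = 115
    n1: int = 19
    seed: int = 0

    def __post_init__(self):
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("target class counts must be >= 1")
        unknown = set(self.effects) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"effects reference unknown features: {sorted(unknown)}")

    def effect_ranking(self) -> list[str]:
        order = sorted(self.effects, key=lambda k: (-abs(self.effects[k]), k))
        return order

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "effects": self.effects, "intercept": self.intercept,
            "noise_sd": self.noise_sd, "n0": self.n0, "n1": self.n1,
            "seed": self.seed}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerativeRiskSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CohortTable:
    """Cohort with the study feature schema plus the binary ``event`` label."""

    frame: pd.DataFrame
    spec: GenerativeRiskSpec | None = None

    def validate(self) -> None:
        df = self.frame
        missing = set(ALL_FEATURES + ["event"]) - set(df.columns)
        if missing:
            raise ValueError(f"missing cohort columns: {sorted(missing)}")
        for col in BINARY_FEATURES + ["event"]:
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"column {col} must be binary")
        for col in ["norm_area_low_tawss", "norm_area_high_osi"]:
            if not df[col].between(0, 1).all():
                raise ValueError(f"column {col} must lie in [0, 1]")
        if not df["vessel_avg_osi"].between(0, 0.5).all():
            raise ValueError("vessel_avg_osi must lie in [0, 0.5]")
        if not df["artery"].isin(["left", "right"]).all():
            raise ValueError("artery must be 'left' or 'right'")
        for col in ["psv", "peak_tawss", "vessel_avg_tawss", "pss",
                    "mean_arterial_pressure", "bmi"]:
            if not (df[col] > 0).all():
                raise ValueError(f"column {col} must be positive")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        table = cls(pd.read_csv(path))
        table.validate()
        return table


def _draw_features(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {
        "artery": np.where(rng.random(n) < 0.5, "left", "right")
    }
    for name, (kind, params, _, _) in _MARGINALS.items():
        if kind == "normal_clip":
            mu, sd, lo, hi = params
            cols[name] = np.clip(rng.normal(mu, sd, n), lo, hi)
        elif kind == "beta_scaled":
            a, b, scale = params
            cols[name] = rng.beta(a, b, n) * scale
        elif kind == "lognormal":
            mu, sd = params
            cols[name] = rng.lognormal(mu, sd, n)
        elif kind == "bernoulli":
            cols[name] = (rng.random(n) < params[0]).astype(int)
    return pd.DataFrame(cols)[ALL_FEATURES]


def event_logit(features: pd.DataFrame, spec: GenerativeRiskSpec) -> np.ndarray:
    """Noise-free logit of the generative event model for given features."""
    logit = np.full(len(features), spec.intercept, dtype=float)
    for name, eff in spec.effects.items():
        _, _, mean, sd = _MARGINALS[name]
        logit += eff * (features[name].to_numpy(dtype=float) - mean) / sd
    return logit


def generate_cohort(spec: GenerativeRiskSpec) -> CohortTable:
    """Cohort with exactly ``spec.n0`` event-free and ``spec.n1`` event rows.

    Features are drawn from the marginals, labels from the logistic ground
    truth; rejection sampling runs until both class counts are met (an error
    is raised after a bounded number of draws if the effect sizes push the
    prevalence so close to 0 or 1 that the counts are unreachable).
    """
    rng = substream(spec.seed, "cohort")
    need0, need1 = spec.n0, spec.n1
    keep0: list[pd.DataFrame] = []
    keep1: list[pd.DataFrame] = []
    total = spec.n0 + spec.n1
    drawn = 0
    max_draws = 2000 * total
    while need0 > 0 or need1 > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                "cohort generation failed: effect sizes/intercept give a "
                "prevalence too extreme to reach the requested class counts"
            )
        batch = max(total, 4 * max(need0, need1))
        feats = _draw_features(rng, batch)
        drawn += batch
        logit = event_logit(feats, spec)
        if spec.noise_sd > 0:
            logit = logit + rng.normal(0.0, spec.noise_sd, batch)
        y = (rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
        if need0 > 0:
            sel = feats[y == 0].iloc[:need0]
            keep0.append(sel)
            need0 -= len(sel)
        if need1 > 0:
            sel = feats[y == 1].iloc[:need1]
            keep1.append(sel)
            need1 -= len(sel)
    df0 = pd.concat(keep0, ignore_index=True)
    df1 = pd.concat(keep1, ignore_index=True)
    df0["event"] = 0
    df1["event"] = 1
    df = pd.concat([df0, df1], ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    table = CohortTable(df, spec)
    table.validate()
    return table
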