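"""Synthetic assay data with planted ground truth.

Three generators emulate the raw data of a plasmid-dependent phage
discovery study, so that every downstream analysis stage can be exercised
and benchmarked without any experimental input:

* two-channel fluorescence plate images of co-culture lawns carrying
  plaques of three phenotypes (red-host-specific, green-host-specific,
  plasmid-dependent), with plaque counts drawn from the Poisson law that
  underlies titer estimation;
* 96-well plate-reader growth curves (10 h at 5-min intervals, OD660-like)
  with phage-driven lysis of tunable strength;
* collections of ~15 kb syntenic genomes generated by substitutions only,
  planted in identity clusters with optional per-gene mutation-rate
  hotspots.

All generators are deterministic given their spec's ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .host_range import GrowthCurveSet, PlateLayout, WellRole
from .plate_vision import PHAGE_CLASSES, ChannelImage, PlateImage, PlaqueClass
from .seq_diversity import Gene, GeneMap, GenomeCollection

__all__ = [
    "PlateTruthSpec",
    "GrowthTruthSpec",
    "LogisticParams",
    "GenomeTruthSpec",
    "sample_plaque_count",
    "generate_plate_image",
    "generate_growth_curves",
    "generate_genome_collection",
    "score_plaque_recovery",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# plaque counts and plate images
# ---------------------------------------------------------------------------

def sample_plaque_count(
    concentration_pfu_per_ml: float,
    plated_volume_ml: float,
    dilution_exponent: int,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Draw a plaque count from Poisson(C * V * 10^-d).

    Plating a volume V of a 10^-d dilution of a sample at concentration C
    deposits on average C*V*10^-d infectious particles, each founding one
    plaque.
    """
    if concentration_pfu_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    if plated_volume_ml <= 0:
        raise ValueError("plated volume must be positive")
    if dilution_exponent < 0:
        raise ValueError("dilution exponent must be >= 0")
    lam = concentration_pfu_per_ml * plated_volume_ml * 10.0 ** (-dilution_exponent)
    return int(_as_rng(rng).poisson(lam))


@dataclass
class PlateTruthSpec:
    """Ground-truth description of one synthetic co-culture plate.

    Concentrations are PFU/mL per phenotype class; ``plaque_radius_log_mean``
    and ``plaque_radius_log_sd`` parameterize a lognormal radius in pixels.
    ``deficit_depth`` is the fractional fluorescence loss at a plaque center
    in each killed channel.  With ``min_separation_px`` set, plaque centers
    are placed by rejection sampling so that disks do not overlap (benchmark
    mode); by default overlaps are allowed, as on real crowded plates.
    """

    plate_diameter_mm: float = 86.0
    image_size_px: tuple[int, int] = (1024, 1024)
    concentrations: dict[PlaqueClass, float] = field(
        default_factory=lambda: {
            PlaqueClass.RED_HOST_PHAGE: 1000.0,
            PlaqueClass.GREEN_HOST_PHAGE: 1000.0,
            PlaqueClass.PLASMID_DEPENDENT: 1000.0,
        }
    )
    plated_volume_ml: float = 0.1
    dilution_exponent: int = 0
    lawn_mean_intensity: tuple[float, float] = (0.55, 0.55)  # (red, green), fraction of range
    lawn_noise_sd: float = 0.01
    plaque_radius_log_mean: float = 2.2   # median ~9 px at ~12 px/mm
    plaque_radius_log_sd: float = 0.25
    deficit_depth: float = 0.9
    min_separation_px: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cls, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"concentration for {cls} must be >= 0")
        if not (0 < self.deficit_depth <= 1):
            raise ValueError("deficit_depth must lie in (0, 1]")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be positive")
        if self.dilution_exponent < 0:
            raise ValueError("dilution exponent must be >= 0")
        if min(self.image_size_px) < 64:
            raise ValueError("image too small to hold a plate disk")
        for v in self.lawn_mean_intensity:
            if not (0 < v <= 1):
                raise ValueError("lawn intensities are fractions of dynamic range in (0, 1]")

    @property
    def plate_radius_px(self) -> float:
        # plate disk fills 95% of the shorter image side
        return 0.475 * min(self.image_size_px)


# which channels a plaque of each class kills
_KILLS = {
    PlaqueClass.RED_HOST_PHAGE: ("red",),
    PlaqueClass.GREEN_HOST_PHAGE: ("green",),
    PlaqueClass.PLASMID_DEPENDENT: ("red", "green"),
}

#: fraction of the radius over which the plaque edge tapers (cosine ramp)
EDGE_TAPER_FRACTION = 0.2


def _render_plaque(factor: np.ndarray, cy: float, cx: float, radius: float,
                   depth: float) -> None:
    """Multiply ``factor`` in place by the soft-edged kill profile of one
    plaque: full depth inside (1 - taper)*radius, cosine ramp to zero at the
    rim."""
    h, w = factor.shape
    r_int = int(math.ceil(radius)) + 1
    y0, y1 = max(0, int(cy) - r_int), min(h, int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(w, int(cx) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    core = radius * (1.0 - EDGE_TAPER_FRACTION)
    profile = np.zeros_like(dist)
    profile[dist <= core] = 1.0
    edge = (dist > core) & (dist <= radius)
    profile[edge] = 0.5 * (1.0 + np.cos(np.pi * (dist[edge] - core) / (radius - core)))
    factor[y0:y1, x0:x1] *= 1.0 - depth * profile


def generate_plate_image(spec: PlateTruthSpec) -> tuple[PlateImage, pd.DataFrame]:
    """Render a synthetic two-channel plate and return it with its truth table.

    Per class, the number of plaques is Poisson(C*V*10^-d); each plaque is a
    soft-edged disk multiplying the lawn by ``1 - deficit_depth`` in every
    channel its phage kills.  Gaussian lawn noise is added after rendering.
    The truth table has one row per planted plaque:
    (plaque_id, class, center_y, center_x, radius_px).
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size_px
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    R = spec.plate_radius_px

    yy, xx = np.mgrid[0:h, 0:w]
    plate_mask = np.hypot(yy - cy0, xx - cx0) <= R

    factors = {
        "red": np.ones((h, w)),
        "green": np.ones((h, w)),
    }

    rows = []
    placed: list[tuple[float, float, float]] = []
    plaque_id = 0
    for cls in PHAGE_CLASSES:
        conc = spec.concentrations.get(cls, 0.0)
        n = sample_plaque_count(conc, spec.plated_volume_ml, spec.dilution_exponent, rng)
        for _ in range(n):
            radius = float(rng.lognormal(spec.plaque_radius_log_mean,
                                         spec.plaque_radius_log_sd))
            if radius >= R:
                raise ValueError(
                    f"sampled plaque radius {radius:.1f} px exceeds the plate radius "
                    f"{R:.1f} px; tighten the radius distribution"
                )
            for attempt in range(10000):
                # uniform over the plate disk eroded by the plaque radius
                r_pos = (R - radius) * math.sqrt(rng.random())
                theta = 2.0 * math.pi * rng.random()
                cy = cy0 + r_pos * math.sin(theta)
                cx = cx0 + r_pos * math.cos(theta)
                if spec.min_separation_px is None:
                    break
                ok = all(
                    math.hypot(cy - py, cx - px) >= radius + pr + spec.min_separation_px
                    for py, px, pr in placed
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    "could not place a non-overlapping plaque; lower the concentrations "
                    "or the separation"
                )
            placed.append((cy, cx, radius))
            for chan in _KILLS[cls]:
                _render_plaque(factors[chan], cy, cx, radius, spec.deficit_depth)
            rows.append(
                {
                    "plaque_id": plaque_id,
                    "class": cls.value,
                    "center_y": cy,
                    "center_x": cx,
                    "radius_px": radius,
                }
            )
            plaque_id += 1

    channels = {}
    for i, chan in enumerate(("red", "green")):
        img = np.zeros((h, w))
        img[plate_mask] = spec.lawn_mean_intensity[i]
        img *= factors[chan]
        if spec.lawn_noise_sd > 0:
            img += rng.normal(0.0, spec.lawn_noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0)
        channels[chan] = ChannelImage(
            data=np.round(img * 65535).astype(np.uint16), channel=chan, bit_depth=16
        )

    truth = pd.DataFrame(
        rows, columns=["plaque_id", "class", "center_y", "center_x", "radius_px"]
    )
    plate = PlateImage(
        red=channels["red"],
        green=channels["green"],
        plated_volume_ml=spec.plated_volume_ml,
        dilution_exponent=spec.dilution_exponent,
        sample=f"synthetic-seed{spec.rng_seed}",
    )
    return plate, truth


def score_plaque_recovery(
    calls, truth: pd.DataFrame, max_center_offset_px: float = 3.0
) -> pd.DataFrame:
    """Score detected plaque calls against a planted truth table.

    Each call is greedily matched (nearest first) to an unmatched truth
    plaque whose center lies within the truth radius plus
    ``max_center_offset_px`` of the call centroid; a match with the same
    class is a true positive.  Returns per-class precision and recall with
    true/predicted counts; classes with no truth or no predictions score
    NaN for the undefined rate.
    """
    from scipy.spatial import cKDTree

    records = []
    if len(truth) and len(calls):
        tree = cKDTree(truth[["center_y", "center_x"]].to_numpy(dtype=float))
        matched: set[int] = set()
        tp_by_class: dict[str, int] = {}
        order = sorted(
            calls,
            key=lambda c: tree.query(c.centroid)[0],
        )
        for call in order:
            dists, idxs = tree.query(call.centroid, k=min(4, len(truth)))
            for dist, idx in zip(np.atleast_1d(dists), np.atleast_1d(idxs)):
                if idx in matched:
                    continue
                limit = truth.iloc[int(idx)]["radius_px"] + max_center_offset_px
                if dist <= limit:
                    matched.add(int(idx))
                    if truth.iloc[int(idx)]["class"] == call.plaque_class.value:
                        name = call.plaque_class.value
                        tp_by_class[name] = tp_by_class.get(name, 0) + 1
                    break
    else:
        tp_by_class = {}

    for cls in PHAGE_CLASSES:
        name = cls.value
        n_true = int((truth["class"] == name).sum()) if len(truth) else 0
        n_pred = sum(1 for c in calls if c.plaque_class.value == name)
        tp = tp_by_class.get(name, 0)
        records.append(
            {
                "class": name,
                "n_true": n_true,
                "n_pred": n_pred,
                "true_positives": tp,
                "precision": tp / n_pred if n_pred else float("nan"),
                "recall": tp / n_true if n_true else float("nan"),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters of one host: initial OD, carrying
    capacity, and per-minute rate."""

    od0: float = 0.05
    carrying_capacity: float = 1.0
    rate_per_min: float = 0.015

    def __post_init__(self) -> None:
        if not (0 < self.od0 < self.carrying_capacity):
            raise ValueError("need 0 < od0 < carrying capacity")

    def curve(self, t_min: np.ndarray) -> np.ndarray:
        e = np.exp(self.rate_per_min * np.asarray(t_min, dtype=float))
        return (self.carrying_capacity * self.od0 * e) / (
            self.carrying_capacity + self.od0 * (e - 1.0)
        )


@dataclass
class GrowthTruthSpec:
    """Ground truth for one plate of synthetic growth curves.

    ``inhibition`` maps (host, phage) to the lysis strength eta in [0, 1]:
    eta=0 leaves the infected well identical in expectation to the host's
    phage-free control, eta=1 applies the full lysis trajectory (logistic
    growth until ``t_lyse_min`` then exponential decay toward the blank).
    Intermediate eta interpolates linearly between the two trajectories.
    """

    duration_min: float = 600.0
    interval_min: float = 5.0
    hosts: dict[str, LogisticParams] = field(default_factory=dict)
    inhibition: dict[tuple[str, str], float] = field(default_factory=dict)
    t_lyse_min: float = 120.0
    decay_rate_per_min: float = 0.02
    blank_od: float = 0.08
    noise_sd: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for pair, eta in self.inhibition.items():
            if not (0.0 <= eta <= 1.0):
                raise ValueError(f"inhibition for {pair} must lie in [0, 1]")
        n_points = self.duration_min / self.interval_min
        if abs(n_points - round(n_points)) > 1e-9:
            raise ValueError("duration must be a multiple of the interval")

    @property
    def timepoints(self) -> np.ndarray:
        n = int(round(self.duration_min / self.interval_min)) + 1
        return np.arange(n) * self.interval_min


def _expected_od(
    spec: GrowthTruthSpec, host: str | None, phage: str | None, role: WellRole,
    t: np.ndarray,
) -> np.ndarray:
    if role == WellRole.CELL_FREE_BLANK or host is None:
        return np.full_like(t, spec.blank_od, dtype=float)
    params = spec.hosts.get(host, LogisticParams())
    growth = params.curve(t)
    if role == WellRole.PHAGE_FREE_CONTROL or phage is None:
        return spec.blank_od + growth
    eta = spec.inhibition.get((host, phage), 0.0)
    lysed = growth.copy()
    after = t > spec.t_lyse_min
    od_at_lysis = params.curve(np.array([spec.t_lyse_min]))[0]
    lysed[after] = od_at_lysis * np.exp(
        -spec.decay_rate_per_min * (t[after] - spec.t_lyse_min)
    )
    return spec.blank_od + (1.0 - eta) * growth + eta * lysed


def generate_growth_curves(
    layout: PlateLayout, spec: GrowthTruthSpec
) -> tuple[GrowthCurveSet, pd.DataFrame]:
    """Simulate OD readings for every well of ``layout``.

    Returns the curve set and a truth table (well, host, phage, eta) giving
    the planted lysis strength of each infected well.
    """
    rng = np.random.default_rng(spec.rng_seed)
    t = spec.timepoints
    data = {}
    truth_rows = []
    for well in sorted(layout.wells):
        cond = layout.wells[well]
        expected = _expected_od(spec, cond.host, cond.phage, cond.role, t)
        if spec.noise_sd > 0:
            expected = expected + rng.normal(0.0, spec.noise_sd, size=t.shape)
        data[well] = expected
        if cond.role == WellRole.INFECTED:
            truth_rows.append(
                {
                    "well": well,
                    "host": cond.host,
                    "phage": cond.phage,
                    "eta": spec.inhibition.get((cond.host, cond.phage), 0.0),
                }
            )
    curves = GrowthCurveSet(timepoints=t, od=pd.DataFrame(data), layout=layout)
    truth = pd.DataFrame(truth_rows, columns=["well", "host", "phage", "eta"])
    return curves, truth


# ---------------------------------------------------------------------------
# genome collections
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruthSpec:
    """Ground truth for a synthetic collection of syntenic phage genomes.

    Isolates are generated by substitutions only (no indels), so sequences
    stay reference-length with gene synteny perfectly conserved, under a
    star-within-star genealogy: each planted cluster descends from an
    ancestor mutated away from the reference, and each isolate from its
    cluster ancestor.  ``within_identity_pct`` and ``between_identity_pct``
    set the expected leaf-leaf identities inside and across clusters and
    are converted to per-branch substitution probabilities
    (mu_within = (1 - within/100)/2 per leaf branch; mu_between chosen so
    cross-cluster pairs diverge to the between target).
    ``gene_multipliers`` (length ``n_genes``) scale the per-site
    substitution probability inside each gene, letting specific genes act
    as SNP hotspots.
    """

    reference_length_bp: int = 15000
    n_genes: int = 31
    cluster_sizes: tuple[int, ...] = (5, 5, 5)
    within_identity_pct: float = 98.0
    between_identity_pct: float = 90.0
    gene_multipliers: tuple[float, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_length_bp < self.n_genes:
            raise ValueError("reference too short to tile the genes")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        if self.between_identity_pct >= self.within_identity_pct:
            raise ValueError(
                "between-cluster identity must be below within-cluster identity"
            )
        if self.gene_multipliers is not None and len(self.gene_multipliers) != self.n_genes:
            raise ValueError("need one rate multiplier per gene")
        if not (0.0 <= self.mu_within <= 0.25 and 0.0 <= self.mu_between <= 0.25):
            raise ValueError("identity targets imply per-site rates outside [0, 0.25]")
        peak = max(self.gene_multipliers or (1.0,))
        if peak * max(self.mu_within, self.mu_between) > 0.25:
            raise ValueError("hotspot multiplier pushes a per-site rate above 0.25")

    @property
    def n_isolates(self) -> int:
        return int(sum(self.cluster_sizes))

    @property
    def mu_within(self) -> float:
        # leaf-leaf pairs inside a cluster differ along two leaf branches
        return (1.0 - self.within_identity_pct / 100.0) / 2.0

    @property
    def mu_between(self) -> float:
        # cross-cluster pairs also differ along two ancestor branches
        total = (1.0 - self.between_identity_pct / 100.0) / 2.0
        return max(total - self.mu_within, 0.0)

    def gene_map(self) -> GeneMap:
        """Tile the reference with ``n_genes`` contiguous non-overlapping
        genes of near-equal length."""
        bounds = np.linspace(0, self.reference_length_bp, self.n_genes + 1).astype(int)
        return GeneMap(
            genes=[
                Gene(gene_id=f"gene{str(i + 1).zfill(2)}", start=int(bounds[i]),
                     end=int(bounds[i + 1]))
                for i in range(self.n_genes)
            ]
        )

    def site_rate_profile(self) -> np.ndarray:
        """Per-site relative substitution rate from the gene multipliers."""
        profile = np.ones(self.reference_length_bp)
        if self.gene_multipliers is not None:
            for gene, mult in zip(self.gene_map(), self.gene_multipliers):
                profile[gene.start : gene.end] = mult
        return profile


def _mutate(codes: np.ndarray, p_site: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p_site, to a uniformly chosen
    different base."""
    mask = rng.random(codes.shape[0]) < p_site
    out = codes.copy()
    shift = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shift) % 4
    return out


def generate_genome_collection(
    spec: GenomeTruthSpec,
) -> tuple[GenomeCollection, GeneMap, dict]:
    """Generate a planted-cluster genome collection.

    Returns the collection (reference id ``REF``), the gene map, and a
    truth dict with the planted cluster label per isolate
    (``cluster_labels``), the realized per-100-bp-window polymorphic site
    counts (``window_variant_sites``), and the branch substitution
    probabilities used.
    """
    rng = np.random.default_rng(spec.rng_seed)
    L = spec.reference_length_bp
    profile = spec.site_rate_profile()
    reference = rng.integers(0, 4, size=L).astype(np.uint8)

    labels: dict[str, int] = {}
    ids: list[str] = []
    seqs: list[np.ndarray] = []
    for k, size in enumerate(spec.cluster_sizes):
        ancestor = _mutate(reference, spec.mu_between * profile, rng)
        for j in range(size):
            leaf = _mutate(ancestor, spec.mu_within * profile, rng)
            iso = f"iso{str(len(ids) + 1).zfill(3)}"
            ids.append(iso)
            labels[iso] = k
            seqs.append(leaf)

    from .seq_diversity import _decode  # shared base/gap alphabet

    collection = GenomeCollection(
        reference_id="REF",
        reference=_decode(reference),
        ids=ids,
        sequences=[_decode(s) for s in seqs],
    )

    stacked = np.stack(seqs)
    polymorphic = (
        (stacked != stacked[0]).any(axis=0) if len(seqs) > 1 else np.zeros(L, dtype=bool)
    )
    window_rows = []
    for start in range(0, L, 100):
        end = min(start + 100, L)
        window_rows.append(
            {"start": start, "end": end, "n_variant_sites": int(polymorphic[start:end].sum())}
        )
    truth = {
        "cluster_labels": labels,
        "window_variant_sites": pd.DataFrame(window_rows),
        "mu_within": spec.mu_within,
        "mu_between": spec.mu_between,
    }
    return collection, spec.gene_map(), truth
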