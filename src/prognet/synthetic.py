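"""Ground-truth generators: cohorts, lesion phantoms, follow-up times.

Every downstream stage is validated against a recoverable truth:

* clinical cohorts are forward-sampled from a known discrete Bayesian
  network whose sink node is the binary survival status; continuous
  prognostic variables (diagnosis age, tumor size, lymph-node counts) are
  produced by sampling a discrete level first and then drawing uniformly
  inside that level's interval, so the equidistant discretization recovers
  the generating level exactly;
* CT-like phantoms carry an ellipsoidal lesion of known analytic diameter
  and volume on a constant background plus additive Gaussian noise;
* two-arm follow-up times are exponential with per-arm hazards and
  administrative censoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import DiscreteBayesianNetwork
from .features import DiscretizationSpec

__all__ = [
    "GroundTruthNetwork",
    "PhantomSpec",
    "FollowupSpec",
    "make_ground_truth",
    "sample_cohort",
    "exact_marginals",
    "make_phantom",
    "simulate_followup",
    "fractional_brownian_surface",
]

OUTCOME = "survival_status"

#: the six prognostic variables retained by the selection stage, each coded
#: as a binary low/high-risk indicator in the default truth
SIGNAL_VARIABLES = (
    "histological_grade",
    "tumor_stage",
    "diagnosis_age",
    "tumor_size",
    "examined_lymph_nodes",
    "positive_lymph_nodes",
)

#: the ten remaining catalog variables, independent of everything by default
NUISANCE_LEVELS = {
    "gender": 2,
    "marital_status": 2,
    "location": 3,
    "affected_side": 2,
    "pathological_type": 3,
    "degree_of_transfer": 2,
    "degree_of_diffusion": 2,
    "lymph_node_accumulation": 2,
    "operation_type": 2,
    "radiotherapy": 2,
}

#: P(death | number of adverse predictor levels): a strong monotone response
#: with a critical risk burden around three adverse factors, so survival
#: status depends on each predictor far more strongly given the others than
#: marginally (the conditional signal structure learning relies on)
DEATH_PROB_BY_RISK_COUNT = (0.02, 0.05, 0.15, 0.85, 0.95, 0.98, 0.98)

#: generator-side equidistant interval specs for the continuous variables
#: (level j occupies the j-th of r equal intervals)
DEFAULT_INTERVALS = {
    "diagnosis_age": DiscretizationSpec(35.0, 85.0, 2),
    "tumor_size": DiscretizationSpec(0.5, 8.5, 2),
    "examined_lymph_nodes": DiscretizationSpec(0.0, 40.0, 2),
    "positive_lymph_nodes": DiscretizationSpec(0.0, 20.0, 2),
}


@dataclass
class GroundTruthNetwork:
    """A validated simulator truth: DAG + CPTs + outcome sink node."""

    network: DiscreteBayesianNetwork
    outcome_node: str
    interval_specs: dict[str, DiscretizationSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome_node not in self.network.nodes:
            raise ValueError("outcome node missing from network")
        if self.network.graph().out_degree(self.outcome_node) != 0:
            raise ValueError("outcome node must have no children")

    @property
    def nodes(self) -> list[str]:
        return self.network.nodes

    @property
    def edges(self) -> list[tuple[str, str]]:
        return self.network.edges


def _random_cpt(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    raw = rng.gamma(1.0, 1.0, size=shape)
    return raw / raw.sum(axis=-1, keepdims=True)


def make_ground_truth(config: dict | None = None) -> GroundTruthNetwork:
    """Build a validated ground-truth network.

    With no config this is the default seven-node truth: six binary
    predictors all pointing into the binary survival status (whose death
    probability rises with the number of adverse levels), plus one
    predictor–predictor edge tumor_stage → positive_lymph_nodes so that
    skeleton discovery faces a non-trivial conditioning case.

    A config dict may instead give ``nodes`` (name → level count),
    ``edges`` (parent → child pairs), and either explicit ``cpts``
    (name → array) or ``random_seed`` for random tables; optional keys:
    ``outcome`` (default ``survival_status``), ``include_nuisance`` (add the
    ten independent catalog variables to the default truth).
    """
    config = dict(config or {})
    if "nodes" in config:
        levels = {k: int(v) for k, v in config["nodes"].items()}
        nodes = sorted(levels)
        edges = [tuple(e) for e in config.get("edges", [])]
        parents: dict[str, tuple[str, ...]] = {v: () for v in nodes}
        for p, c in edges:
            parents[c] = tuple(sorted(parents[c] + (p,)))
        if "cpts" in config:
            cpts = {v: np.asarray(config["cpts"][v], dtype=float) for v in nodes}
        else:
            rng = np.random.default_rng(config.get("random_seed", 0))
            cpts = {v: _random_cpt(rng, tuple(levels[p] for p in parents[v]) + (levels[v],))
                    for v in nodes}
        outcome = config.get("outcome")
        net = DiscreteBayesianNetwork(nodes, levels, parents, cpts, outcome=outcome)
        return GroundTruthNetwork(net, outcome if outcome else nodes[-1],
                                  config.get("interval_specs", {}))

    levels = {v: 2 for v in SIGNAL_VARIABLES}
    levels[OUTCOME] = 2
    parents = {v: () for v in SIGNAL_VARIABLES}
    parents["positive_lymph_nodes"] = ("tumor_stage",)
    parents[OUTCOME] = tuple(sorted(SIGNAL_VARIABLES))
    cpts: dict[str, np.ndarray] = {
        "histological_grade": np.array([0.55, 0.45]),
        "tumor_stage": np.array([0.5, 0.5]),
        "diagnosis_age": np.array([0.5, 0.5]),
        "tumor_size": np.array([0.5, 0.5]),
        "examined_lymph_nodes": np.array([0.5, 0.5]),
        # advanced stage strongly raises the positive-node burden
        "positive_lymph_nodes": np.array([[0.8, 0.2], [0.2, 0.8]]),
    }
    out_shape = tuple(2 for _ in SIGNAL_VARIABLES) + (2,)
    out = np.empty(out_shape)
    for cfg in itertools.product(*(range(2) for _ in SIGNAL_VARIABLES)):
        # parents indexed in sorted order inside the CPT
        p_death = DEATH_PROB_BY_RISK_COUNT[sum(cfg)]
        out[cfg] = (1.0 - p_death, p_death)
    cpts[OUTCOME] = out

    if config.get("include_nuisance"):
        rng = np.random.default_rng(config.get("random_seed", 0))
        for v, k in NUISANCE_LEVELS.items():
            levels[v] = k
            parents[v] = ()
            raw = rng.uniform(0.3, 0.7, size=k)
            cpts[v] = raw / raw.sum()

    nodes = sorted(levels)
    net = DiscreteBayesianNetwork(nodes, levels, parents, cpts, outcome=OUTCOME)
    return GroundTruthNetwork(net, OUTCOME, dict(DEFAULT_INTERVALS))


def sample_cohort(truth: GroundTruthNetwork, n: int, seed: int,
                  continuous: bool = True) -> pd.DataFrame:
    """Forward-sample ``n`` patient rows in topological order.

    Discrete columns hold integer levels.  With ``continuous=True`` every
    variable carrying an interval spec is emitted as a continuous value
    drawn uniformly inside its sampled level's interval (strictly inside,
    so the equidistant discretization is exactly invertible).
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    net = truth.network
    order = net.topological_order()
    cols: dict[str, np.ndarray] = {}
    for v in order:
        ps = net.parents[v]
        cpt = net.cpts[v]
        if not ps:
            probs = np.broadcast_to(cpt, (n, net.levels[v]))
        else:
            idx = tuple(cols[p] for p in ps)
            probs = cpt[idx]
        u = rng.random(n)
        cols[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    df = pd.DataFrame({v: cols[v] for v in net.nodes}).astype(int)
    if continuous:
        for v, spec in truth.interval_specs.items():
            if v not in df.columns:
                continue
            j = df[v].to_numpy()
            # open interval: keep draws strictly inside the level's bin
            u = rng.uniform(1e-6, 1.0 - 1e-6, size=n)
            df[v] = spec.x_min + (j + u) * spec.d
    return df


def exact_marginals(truth: GroundTruthNetwork) -> dict[str, np.ndarray]:
    """Marginal distribution of every node by exact enumeration of the joint."""
    net = truth.network
    order = net.topological_order()
    # joint built by successive broadcasting over node axes in `order`
    axis = {v: i for i, v in enumerate(order)}
    joint = np.ones([1] * len(order))
    for v in order:
        cpt = net.cpts[v]
        src = list(net.parents[v]) + [v]
        perm_shape = [net.levels[s] for s in src]
        arr = cpt.reshape(perm_shape)
        expand = [1] * len(order)
        for s in src:
            expand[axis[s]] = net.levels[s]
        # move each source axis into joint position
        dest = sorted(src, key=lambda s: axis[s])
        arr = np.moveaxis(arr, [src.index(s) for s in dest], range(len(src)))
        joint = joint * arr.reshape(expand)
    out = {}
    for v in order:
        axes = tuple(i for i in range(len(order)) if i != axis[v])
        out[v] = joint.sum(axis=axes)
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of an ellipsoidal-lesion phantom image stack.

    Lengths are millimetres; ``shape`` is (slices, rows, cols); the lesion
    center is in physical coordinates with voxel centers at
    (index + 0.5) · spacing.
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] = (16.0, 32.0, 32.0)
    semi_axes: tuple[float, float, float] = (10.0, 12.0, 12.0)
    lesion_intensity: float = 190.0
    background_intensity: float = 70.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for i in (self.lesion_intensity, self.background_intensity):
            if not 0 <= i <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        for c, a, n, sp in zip(self.center, self.semi_axes, self.shape, self.spacing):
            if c - a < 0 or c + a > n * sp:
                raise ValueError("lesion extends outside the image grid")


@dataclass(frozen=True)
class LesionMeasurement:
    """Longest in-plane diameter (mm) and volume (cm³) of one lesion."""

    diameter_mm: float
    volume_cm3: float
    component_id: int = 1
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm < 0 or self.volume_cm3 < 0:
            raise ValueError("measurements must be non-negative")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, LesionMeasurement]:
    """Phantom image stack, exact lesion mask, and the analytic measurement.

    The analytic longest in-plane diameter is twice the larger in-plane
    (row/col) semi-axis; the analytic volume is (4/3)·π·a·b·c in cm³.
    """
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = np.meshgrid(
        (np.arange(spec.shape[0]) + 0.5) * spec.spacing[0],
        (np.arange(spec.shape[1]) + 0.5) * spec.spacing[1],
        (np.arange(spec.shape[2]) + 0.5) * spec.spacing[2],
        indexing="ij",
    )
    az, ay, ax = spec.semi_axes
    cz, cy, cx = spec.center
    mask = (((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2
            + ((xx - cx) / ax) ** 2) <= 1.0
    img = np.full(spec.shape, spec.background_intensity, dtype=float)
    img[mask] = spec.lesion_intensity
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    img = np.clip(img, 0.0, 255.0)
    diameter = 2.0 * max(ay, ax)
    volume = (4.0 / 3.0) * np.pi * az * ay * ax / 1000.0
    return img, mask, LesionMeasurement(diameter, volume)


@dataclass(frozen=True)
class FollowupSpec:
    """Two-arm exponential follow-up with administrative censoring.

    Hazards are per-month event rates; the default medians ln2/λ are 7.1
    months (research arm) and 4.8 months (control arm).
    """

    hazards: dict[str, float] = field(
        default_factory=lambda: {"research": np.log(2) / 7.1,
                                 "control": np.log(2) / 4.8})
    arm_sizes: dict[str, int] = field(
        default_factory=lambda: {"research": 20, "control": 20})
    censor_months: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.hazards) != set(self.arm_sizes):
            raise ValueError("hazards and arm_sizes must name the same arms")
        if any(h <= 0 for h in self.hazards.values()):
            raise ValueError("hazards must be positive")
        if any(n <= 0 for n in self.arm_sizes.values()):
            raise ValueError("arm sizes must be positive")
        if self.censor_months < 0:
            raise ValueError("censoring time must be non-negative")


def simulate_followup(spec: FollowupSpec) -> pd.DataFrame:
    """Per-patient (arm, time, event): exponential event times censored at
    the administrative cut-off."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for arm in sorted(spec.hazards):
        t = rng.exponential(1.0 / spec.hazards[arm], size=spec.arm_sizes[arm])
        event = t <= spec.censor_months
        frames.append(pd.DataFrame({
            "arm": arm,
            "time_months": np.minimum(t, spec.censor_months),
            "event": event.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def fractional_brownian_surface(n: int, hurst: float, seed: int = 0) -> np.ndarray:
    """8-bit fractional Brownian surface by spectral synthesis.

    Power spectral density ∝ f^−(2H+2); the fractal dimension of such a
    surface is ≈ 3 − H, so a low Hurst exponent gives a rougher image.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    f = np.fft.fftfreq(n)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0
    amplitude = radius ** (-(hurst + 1.0))
    amplitude[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=(n, n))
    spectrum = amplitude * np.exp(1j * phase)
    surf = np.real(np.fft.ifft2(spectrum))
    surf -= surf.min()
    if surf.max() > 0:
        surf /= surf.max()
    return np.round(surf * 255.0)
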