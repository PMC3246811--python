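"""Synthetic geometry tables emulating classic crystal-structure analyses.

Each generator emulates the kind of spreadsheet a substructure search over a
crystal-structure database would export, so the whole analysis stack can be
exercised without any licensed database:

* :func:`gen_furanoside_table` — five endocyclic torsions of a
  five-membered (furanose-like) ring following the pseudorotation model
  τⱼ = τₘ·cos(P + 144°·j): a phase angle P and puckering amplitude τₘ
  generate all five torsions, so noiseless data lie on an exact 2-plane and
  two phase clusters (C2′-endo near P = 162°, C3′-endo near P = 18°)
  reproduce the classic two-cluster PCA score plot.
* :func:`gen_hbond_table` — hydrogen-bond D—H⋯A angle θ and H⋯A distance
  with the geometric sin θ orientational bias built in: the deviation from
  linearity ψ = 180° − θ is drawn from a density ∝ sin ψ · exp(κ cos ψ),
  which at κ = 0 is the pure cone-of-approach bias (uniform directions on a
  sphere) and at large κ a strongly linearity-preferring interaction.
* :func:`gen_symmetric_fragment_table` — k topologically equivalent bond
  lengths per fragment (an octahedral M—L query) with shared per-fragment
  offsets, for exercising symmetry pooling.
* :func:`gen_halide_table` — hydrogen-bond angles to several halide
  acceptor groups with an integer group code, for the selected-vs-rest
  t-test workflow.

All generators draw from a single ``numpy.random.default_rng(seed)`` stream
in a fixed, documented order, so output is bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Descriptor, GeometryTable
from .descriptive import wrap_degrees

__all__ = [
    "PseudorotationParams",
    "HbondGenParams",
    "gen_furanoside_table",
    "gen_hbond_table",
    "gen_symmetric_fragment_table",
    "gen_halide_table",
]

#: the two classic furanose pucker clusters: (P centre deg, P sd deg, weight)
DEFAULT_CLUSTERS = ((162.0, 8.0, 0.5), (18.0, 8.0, 0.5))


@dataclass(frozen=True)
class PseudorotationParams:
    """Two-parameter puckering model for a five-membered ring.

    ``tau_m`` is the puckering amplitude in degrees (39° is typical of
    furanose sugars); ``phase_step`` the 144° spacing between successive
    endocyclic torsions; ``noise_sd`` the standard deviation in degrees of
    wrapped-normal noise added independently to each torsion.
    """

    tau_m: float = 39.0
    phase_step: float = 144.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class HbondGenParams:
    """Hydrogen-bond geometry generator settings.

    ``kappa`` (unitless, ≥ 0) concentrates the deviation-from-linearity
    ψ = 180° − θ toward 0: κ = 0 gives the pure sin ψ cone-of-approach
    density (uniform orientations), large κ a strongly linear donor.
    ``d_mean``/``d_sd`` set the H⋯A distance in Å and ``d_angle_slope``
    (Å/deg) couples distance to ψ, emulating the short-bond/linear-donor
    trend of real hydrogen bonds.
    """

    kappa: float = 5.0
    d_mean: float = 1.9
    d_sd: float = 0.08
    d_angle_slope: float = 0.004

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.d_sd < 0:
            raise ValueError("d_sd must be non-negative")


def _ids(prefix: str, n: int) -> np.ndarray:
    return np.array([f"{prefix}{i:06d}" for i in range(1, n + 1)], dtype=object)


def gen_furanoside_table(
    n: int,
    clusters: Sequence[tuple[float, float, float]] = DEFAULT_CLUSTERS,
    params: PseudorotationParams = PseudorotationParams(),
    seed: int | None = None,
    uniform_phase: bool = False,
) -> GeometryTable:
    """Five endocyclic ring torsions TOR1..TOR5 from a pseudorotation mixture.

    Draw order per call: cluster labels (n), phase angles (n), then the
    n×5 torsion noise block.  Each row picks a cluster by weight, draws
    P ~ wrapped-normal(P_centre, P_sd) and sets
    τⱼ = τₘ·cos(P + 144°·j) + noise, wrapped to [−180°, 180°).
    With ``uniform_phase`` the cluster mixture is replaced by
    P ~ uniform[0°, 360°), sweeping the whole pseudorotation pathway.
    A CLUSTER integer column records the generating cluster.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not clusters and not uniform_phase:
        raise ValueError("need at least one phase cluster")
    rng = np.random.default_rng(seed)
    if uniform_phase:
        labels = np.zeros(n, dtype=int)
        phases = rng.uniform(0.0, 360.0, size=n)
    else:
        weights = np.array([c[2] for c in clusters], dtype=float)
        if np.any(weights <= 0):
            raise ValueError("cluster weights must be positive")
        weights /= weights.sum()
        labels = rng.choice(len(clusters), size=n, p=weights)
        centres = np.array([c[0] for c in clusters])
        sds = np.array([c[1] for c in clusters])
        phases = centres[labels] + rng.normal(0.0, 1.0, size=n) * sds[labels]
    noise = rng.normal(0.0, params.noise_sd, size=(n, 5)) if params.noise_sd > 0 else 0.0
    j = np.arange(5)
    tors = params.tau_m * np.cos(np.deg2rad(phases[:, None] + params.phase_step * j))
    tors = wrap_degrees(tors + noise)
    data = pd.DataFrame({f"TOR{k + 1}": tors[:, k] for k in range(5)})
    data["CLUSTER"] = labels + 1
    descs = {
        f"TOR{k + 1}": Descriptor(f"TOR{k + 1}", "circular", "deg") for k in range(5)
    }
    descs["CLUSTER"] = Descriptor("CLUSTER", "integer")
    return GeometryTable(_ids("FUR", n), np.ones(n, dtype=int), data, descs)


def sample_linearity_deviation(
    n: int, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ψ on [0°, 180°] from density ∝ sin ψ · exp(κ cos ψ).

    Rejection sampling from the sin ψ proposal (cos ψ uniform on [−1, 1])
    with acceptance probability exp(κ(cos ψ − 1)); the mean acceptance rate
    is (1 − e^{−2κ})/(2κ) ≥ e^{−κ}, so the expected number of proposal
    rounds stays modest for the κ values of interest.
    """
    out = np.empty(n)
    have = 0
    while have < n:
        todo = n - have
        # batch size padded by the inverse acceptance rate
        rate = (1 - np.exp(-2 * kappa)) / (2 * kappa) if kappa > 0 else 1.0
        m = int(todo / max(rate, 1e-6) * 1.2) + 16
        c = rng.uniform(-1.0, 1.0, size=m)
        u = rng.uniform(0.0, 1.0, size=m)
        keep = c[u <= np.exp(kappa * (c - 1.0))]
        take = keep[: min(todo, keep.size)]
        out[have : have + take.size] = take
        have += take.size
    return np.rad2deg(np.arccos(out))


def gen_hbond_table(
    n: int,
    params: HbondGenParams = HbondGenParams(),
    seed: int | None = None,
) -> GeometryTable:
    """Hydrogen-bond geometry: THETA (D—H⋯A angle, deg) and DIST (H⋯A, Å).

    θ = 180° − ψ with ψ drawn by :func:`sample_linearity_deviation`; DIST is
    d_mean + d_angle_slope·ψ plus normal noise.  θ is stored as a *linear*
    descriptor on [0°, 180°] — bond angles are not periodic over 360°.
    Draw order: the ψ rejection stream, then the distance noise block.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    psi = sample_linearity_deviation(n, params.kappa, rng)
    theta = 180.0 - psi
    dist = params.d_mean + params.d_angle_slope * psi + rng.normal(
        0.0, params.d_sd, size=n
    )
    data = pd.DataFrame({"THETA": theta, "DIST": dist})
    descs = {
        "THETA": Descriptor("THETA", "linear", "deg"),
        "DIST": Descriptor("DIST", "linear", "Å"),
    }
    return GeometryTable(_ids("HBD", n), np.ones(n, dtype=int), data, descs)


def gen_symmetric_fragment_table(
    n: int,
    k: int = 6,
    mean: float = 1.90,
    sd_within: float = 0.015,
    sd_between: float = 0.010,
    seed: int | None = None,
) -> GeometryTable:
    """k topologically equivalent bond lengths D1..Dk per fragment, in Å.

    Each row draws a fragment-level offset ~ N(0, sd_between²) shared by its
    k bonds, then each bond ~ N(mean + offset, sd_within²) — so the pooled
    distribution over all k·n values has variance sd_within² + sd_between².
    Draw order: offsets (n), then the n×k within-fragment block.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, sd_between, size=n)
    vals = rng.normal(0.0, sd_within, size=(n, k)) + mean + offsets[:, None]
    data = pd.DataFrame({f"D{j + 1}": vals[:, j] for j in range(k)})
    descs = {f"D{j + 1}": Descriptor(f"D{j + 1}", "linear", "Å") for j in range(k)}
    return GeometryTable(_ids("SYM", n), np.ones(n, dtype=int), data, descs)


def gen_halide_table(
    n_per_group: int,
    group_means: Mapping[int, float] | None = None,
    sd: float = 10.0,
    seed: int | None = None,
) -> GeometryTable:
    """Hydrogen-bond ANGLE (deg) to several halide acceptors, HAL group code.

    ``group_means`` maps integer halide codes (e.g. 1=Cl, 2=Br, 3=I) to mean
    D—H⋯A angles in degrees; groups share a common normal sd.  Draw order:
    one angle block per group, in ascending code order.
    """
    if group_means is None:
        group_means = {1: 160.0, 2: 160.0, 3: 160.0}
    if len(group_means) < 2:
        raise ValueError("need at least two halide groups")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    angles, codes = [], []
    for code in sorted(group_means):
        angles.append(rng.normal(group_means[code], sd, size=n_per_group))
        codes.append(np.full(n_per_group, code, dtype=int))
    data = pd.DataFrame(
        {"ANGLE": np.concatenate(angles), "HAL": np.concatenate(codes)}
    )
    n = len(data)
    descs = {
        "ANGLE": Descriptor("ANGLE", "linear", "deg"),
        "HAL": Descriptor("HAL", "integer"),
    }
    return GeometryTable(_ids("HAL", n), np.ones(n, dtype=int), data, descs)
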