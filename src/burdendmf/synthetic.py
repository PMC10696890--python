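"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis needs — a hub-bearing bilateral connectome, cohort
burden maps with realistic means, and "empirical" BOLD targets produced by
the forward model itself with known ground-truth gain parameters — is
generated here as a pure function of (spec, seed), so the full fitting and
evaluation machinery is exercisable without any imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bold import HemodynamicConstants, downsample_to_tr, rates_to_bold
from .connectome import StructuralConnectome, log_normalize
from .dmf import (
    BurdenMap,
    DMFParameters,
    FICWeights,
    GainParameters,
    calibrate_fic,
    compute_gains,
    integrate,
)

__all__ = [
    "SyntheticCohortSpec",
    "COHORT_BURDEN_MEANS",
    "COHORT_SIZES",
    "DEFAULT_TRUE_GAINS",
    "gen_connectome",
    "gen_burden_maps",
    "gen_target_bold",
]

#: cohort mean SUVR loads (amyloid-beta, tau) the generator reproduces
COHORT_BURDEN_MEANS = {
    "HC": (1.31, 1.53),
    "MCI": (1.52, 1.80),
    "AD": (2.01, 2.46),
}

#: reference cohort sizes (used e.g. for biomarker-threshold weighting)
COHORT_SIZES = {"HC": 17, "MCI": 9, "AD": 10}

#: ground-truth gains for recovery experiments: the reported AD-stage
#: coefficient pattern (s_E_abeta=2.3, s_E_tau=-2.6, s_I_abeta=-2.5, biases
#: ~0) scaled by 1/10 so that SUVR-scale burdens keep every regional gain
#: positive (the unscaled values drive the gain polynomial negative, which
#: the clamp would flatten into a non-identifiable regime)
DEFAULT_TRUE_GAINS = GainParameters(
    s_E_abeta=0.23, s_E_tau=-0.26, s_I_abeta=-0.25
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition defaults for the synthetic cohort.

    Desk-scale by construction: 40 regions and a handful of subjects per
    cohort keep every stage of the pipeline runnable in minutes.
    """

    n_regions: int = 40
    n_subjects: dict = field(
        default_factory=lambda: {"HC": 5, "MCI": 3, "AD": 3}
    )
    burden_means: dict = field(default_factory=lambda: dict(COHORT_BURDEN_MEANS))
    burden_cv: float = 0.25          # regional coefficient of variation
    smoothness: float = 3.0          # squared-exponential length-scale (nodes)
    intermap_correlation: float = 0.5  # target abeta-tau spatial correlation
    strength_loading: float = 0.6    # loading of burden onto node strength
    true_gains: GainParameters = DEFAULT_TRUE_GAINS
    master_seed: int = 0

    def __post_init__(self):
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 4")
        for cohort, (a, t) in self.burden_means.items():
            if a <= 0 or t <= 0:
                raise ValueError(f"burden means must be positive ({cohort})")


def gen_connectome(n_regions: int = 40, seed: int = 0,
                   hub_fraction: float = 0.1) -> StructuralConnectome:
    """Symmetric bilateral connectome with homotopic links and hubs.

    Two hemispheres of ``n_regions/2`` nodes each: intra-hemispheric weights
    decay with inter-node distance (index distance as a 1-D proxy), strong
    homotopic inter-hemispheric links pair each node with its mirror, and a
    designated subset of node pairs gets elevated strength, emulating the
    subcortical hubs of group-averaged tractography. Deterministic per seed.
    """
    if n_regions % 2:
        raise ValueError("n_regions must be even (homotopic pairing)")
    rng = np.random.default_rng(seed)
    half = n_regions // 2
    idx = np.arange(half)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    intra = np.exp(-dist / 2.0) * rng.lognormal(0.0, 0.3, (half, half))
    intra = (intra + intra.T) / 2.0
    np.fill_diagonal(intra, 0.0)

    W = np.zeros((n_regions, n_regions))
    W[:half, :half] = intra
    # contralateral hemisphere: same topology, mild weight jitter
    jitter = rng.lognormal(0.0, 0.1, (half, half))
    contra = intra * (jitter + jitter.T) / 2.0
    W[half:, half:] = contra
    # homotopic links: strong mirror-to-mirror connections
    homotopic = 1.5 * rng.lognormal(0.0, 0.2, half)
    W[idx, idx + half] = homotopic
    W[idx + half, idx] = homotopic
    # hubs: last nodes of each hemisphere get elevated strength, emulating
    # subcortical hubs
    n_hubs = max(1, int(round(hub_fraction * half)))
    hubs = np.concatenate([idx[-n_hubs:], idx[-n_hubs:] + half])
    W[hubs, :] *= 3.0
    W[:, hubs] *= 3.0
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    ids = tuple(f"L{i:03d}" for i in range(half)) + tuple(
        f"R{i:03d}" for i in range(half)
    )
    return StructuralConnectome(W, ids, normalized=False)


def hub_nodes(n_regions: int, hub_fraction: float = 0.1) -> np.ndarray:
    """Indices of the designated hub nodes of :func:`gen_connectome`."""
    half = n_regions // 2
    n_hubs = max(1, int(round(hub_fraction * half)))
    base = np.arange(half - n_hubs, half)
    return np.concatenate([base, base + half])


def _smooth_field(n: int, length_scale: float, rng) -> np.ndarray:
    """Zero-mean, unit-variance field with squared-exponential correlation
    over node indices, mirrored across hemispheres."""
    half = n // 2
    idx = np.arange(half)
    d2 = (idx[:, None] - idx[None, :]) ** 2
    K = np.exp(-0.5 * d2 / length_scale**2) + 1e-8 * np.eye(half)
    L = np.linalg.cholesky(K)
    z_l = L @ rng.standard_normal(half)
    z_r = 0.8 * z_l + 0.6 * (L @ rng.standard_normal(half))  # partial homology
    z = np.concatenate([z_l, z_r])
    return (z - z.mean()) / z.std()


def gen_burden_maps(
    spec: SyntheticCohortSpec, cohort: str, subject_index: int = 0,
    intermap_correlation: float | None = None,
    sc: StructuralConnectome | None = None,
) -> tuple[BurdenMap, BurdenMap]:
    """Spatially smooth positive (abeta, tau) maps with cohort-level means.

    Fields are squared-exponential-correlated over node indices; the tau
    field shares a controllable fraction of the amyloid field's spatial
    pattern (subject-level abeta-tau correlations in vivo span roughly
    0.1 to 0.9). When a connectome ``sc`` is given, both fields also carry a
    fixed loading (``spec.strength_loading``) onto standardized log node
    strength, reproducing the preferential accumulation of pathology in
    highly connected hub regions; this couples the burden topography to the
    network topography, so spatially permuting a map genuinely rearranges
    which dynamically important nodes carry burden. Values are SUVR-like:
    mean at the cohort target, spread ``burden_cv`` times the mean, floored
    at a small positive value.
    """
    if cohort not in spec.burden_means:
        raise ValueError(f"unknown cohort {cohort!r}")
    rho = (spec.intermap_correlation if intermap_correlation is None
           else intermap_correlation)
    seed = np.random.SeedSequence(
        [spec.master_seed, {"HC": 0, "MCI": 1, "AD": 2}[cohort], subject_index]
    )
    rng = np.random.default_rng(seed)
    mean_a, mean_t = spec.burden_means[cohort]
    z_a = _smooth_field(spec.n_regions, spec.smoothness, rng)
    z_ind = _smooth_field(spec.n_regions, spec.smoothness, rng)
    # orthogonalize the independent component so the realized sample
    # correlation between the standardized fields is exactly rho (smooth
    # fields have few effective degrees of freedom, so without this the
    # chance correlation between "independent" draws is routinely > 0.5)
    z_ind = z_ind - (z_ind @ z_a) / (z_a @ z_a) * z_a
    z_ind = (z_ind - z_ind.mean()) / z_ind.std()
    z_t = rho * z_a + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
    if sc is not None and spec.strength_loading > 0.0:
        w = spec.strength_loading
        if not 0.0 <= w <= 1.0:
            raise ValueError("strength_loading must be in [0, 1]")
        s = np.log1p(sc.weights.sum(axis=1))
        s = (s - s.mean()) / s.std()
        z_a = w * s + np.sqrt(1.0 - w**2) * z_a
        z_t = w * s + np.sqrt(1.0 - w**2) * z_t
    sid = f"{cohort}{subject_index:03d}"
    abeta = np.maximum(mean_a * (1.0 + spec.burden_cv * z_a), 0.05)
    tau = np.maximum(mean_t * (1.0 + spec.burden_cv * z_t), 0.05)
    return (
        BurdenMap(abeta, protein="abeta", subject_id=sid),
        BurdenMap(tau, protein="tau", subject_id=sid),
    )


def gen_target_bold(
    sc: StructuralConnectome,
    abeta: BurdenMap,
    tau: BurdenMap,
    gp_true: GainParameters,
    G: float,
    duration_s: float = 300.0,
    tr_s: float = 3.0,
    seed: int = 0,
    burn_in_s: float = 10.0,
    params: DMFParameters | None = None,
    fic: FICWeights | None = None,
    hemo: HemodynamicConstants | None = None,
) -> np.ndarray:
    """Forward-model "empirical" BOLD target with known ground truth.

    Full pipeline: FIC calibration at homogeneous gains (unless a
    pre-calibrated ``fic`` is supplied), network integration with the
    burden-derived gains, hemodynamic transform, burn-in discard and TR
    downsampling. Returns a regions x volumes matrix with
    floor((duration - burn_in)/TR) volumes.
    """
    p = (params or DMFParameters()) if G is None else \
        _with_G(params or DMFParameters(), G)
    if fic is None:
        fic = calibrate_fic(sc, None, p, seed=seed)
    gains = compute_gains(abeta, tau, gp_true)
    sim = integrate(sc, fic, gains, p, duration_s * 1000.0, seed)
    bold = rates_to_bold(sim.r_E, p.dt, hemo)
    return downsample_to_tr(bold, p.dt, tr_s, burn_in_s)


def _with_G(p: DMFParameters, G: float) -> DMFParameters:
    from dataclasses import replace

    return replace(p, G=G)
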