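"""Calibrated synthetic serum N-glycomics cohort.

Generates everything the analysis pipeline consumes — a glycan library,
per-subject true abundance vectors, triplicate MALDI-style peak lists with
mass jitter and noise peaks, and clinical covariates (CA125, HE4) — for a
three-group ovarian-disease study design (healthy controls n=60, benign
neoplasms n=70, cancer n=70 split into early and late stages).

Calibration proceeds in three steps:

1. ``calibrate_group_means`` turns a set of derived-trait targets (group
   mean percentages of Man, G0/G1/G2, F, B and S1-S4 traits) into a
   per-glycan mean abundance vector by iterative proportional fitting over
   the overlapping trait-group constraints.
2. ``sample_subjects`` perturbs the group mean on the log scale
   (logistic-normal, one dispersion parameter per group tuned by bisection
   so the across-subject SD of total sialylation matches its target) and
   renormalizes each subject to 100%.
3. ``emit_peaklists`` / ``emit_covariates`` add the measurement layer:
   ppm-scale mass jitter, per-peak lognormal intensity scatter, uniform
   noise peaks, and a CA125 covariate whose empirical Pearson correlations
   with chosen traits are calibrated to target values (HE4 is drawn
   independently of the glycome but shifted between groups).

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .glycan_core import GlycanAnnotation, MassConfig, theoretical_mz
from .library import default_library, write_library
from .spectra import GlycanProfile, PeakList, write_peaklist_csv
from .traits import compute_traits, traits_to_frame

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SyntheticCohort",
    "GROUP_TRAIT_TARGETS",
    "normal_group_targets",
    "calibrate_group_means",
    "sample_subjects",
    "emit_peaklists",
    "emit_covariates",
    "generate_cohort",
    "write_cohort",
]

# Group-level calibration targets: derived-trait mean and across-subject SD
# (percent of total glycan signal) for the benign-neoplasm group and the
# early-stage / late-stage cancer groups.  The neutral-fucosylation entry is
# reconciled with the additivity identity F neutral = F total - F sialo.
GROUP_TRAIT_TARGETS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "benign": {
        "man": (2.98, 0.64), "g0": (2.94, 0.82), "g1": (4.38, 0.74), "g2": (3.35, 0.69),
        "g_total": (7.73, 1.25), "f_neutral": (6.80, 1.70), "f_sialo": (17.10, 2.03),
        "f_total": (23.90, 3.00), "b_neutral": (3.36, 0.66), "b_sialo": (8.35, 1.46),
        "b_total": (11.72, 1.88), "s1": (20.71, 2.87), "s2": (57.02, 5.21),
        "s3": (3.31, 0.69), "s4": (1.07, 0.33), "s_total": (82.11, 3.51),
    },
    "early": {
        "man": (2.95, 0.77), "g0": (2.96, 1.01), "g1": (4.07, 1.02), "g2": (3.08, 0.90),
        "g_total": (7.16, 1.83), "f_neutral": (6.27, 1.70), "f_sialo": (15.79, 3.01),
        "f_total": (22.06, 4.44), "b_neutral": (3.28, 1.01), "b_sialo": (7.52, 1.59),
        "b_total": (10.80, 2.45), "s1": (20.50, 4.82), "s2": (57.48, 7.69),
        "s3": (3.86, 0.99), "s4": (1.15, 0.48), "s_total": (82.99, 4.35),
    },
    "late": {
        "man": (3.08, 0.79), "g0": (3.41, 0.99), "g1": (4.42, 1.18), "g2": (3.25, 1.48),
        "g_total": (7.67, 2.32), "f_neutral": (6.48, 1.68), "f_sialo": (16.79, 2.60),
        "f_total": (23.27, 3.68), "b_neutral": (3.48, 1.00), "b_sialo": (7.79, 1.54),
        "b_total": (11.27, 2.22), "s1": (19.78, 7.16), "s2": (56.56, 10.83),
        "s3": (4.17, 1.00), "s4": (1.33, 0.45), "s_total": (81.84, 4.69),
    },
}

# Pearson correlation targets between CA125 and derived traits over the
# combined benign + cancer cohort.
DEFAULT_CORRELATION_TARGETS: Dict[str, float] = {
    "s_total": -0.26,
    "man": 0.29,
    "g0": 0.23,
    "g1": 0.28,
}


def normal_group_targets(
    benign: Mapping[str, Tuple[float, float]] | None = None, delta_sd: float = 1.0
) -> Dict[str, Tuple[float, float]]:
    """Healthy-control targets derived from the benign column.

    The control group is not tabulated alongside the disease groups, so its
    targets are a synthetic convention: the benign means shifted by
    ``delta_sd`` benign SDs in the directions the disease groups move away
    from controls (lower oligomannose, agalactosylation and neutral
    bisection; higher total sialylation, spread proportionally over S1-S4).
    """
    b = dict(benign if benign is not None else GROUP_TRAIT_TARGETS["benign"])
    out = dict(b)
    for trait in ("man", "g0", "b_neutral"):
        mean, sd = b[trait]
        out[trait] = (max(mean - delta_sd * sd, 0.05), sd)
    s_mean, s_sd = b["s_total"]
    new_s = min(s_mean + delta_sd * s_sd, 99.0)
    scale = new_s / s_mean
    for k in ("s1", "s2", "s3", "s4"):
        m, sd = b[k]
        out[k] = (m * scale, sd)
    out["s_total"] = (new_s, s_sd)
    out["b_total"] = (out["b_neutral"][0] + out["b_sialo"][0], b["b_total"][1])
    out["g_total"] = (out["g1"][0] + out["g2"][0], b["g_total"][1])
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Study design and noise model of the synthetic cohort."""

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 60, "benign": 70, "cancer": 70}
    )
    trait_targets: Mapping[str, Mapping[str, Tuple[float, float]]] = field(
        default_factory=lambda: {**GROUP_TRAIT_TARGETS, "normal": normal_group_targets()}
    )
    correlation_targets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_TARGETS)
    )
    mz_jitter_ppm: float = 30.0      # per-spot coherent calibration error (ppm, 1 sd)
    centroid_jitter_ppm: float = 10.0  # independent per-peak centroiding noise (ppm, 1 sd)
    noise_peaks: int = 5
    noise_intensity: float = 0.05    # max noise-peak intensity, % of total signal
    spot_cv: float = 0.15            # per-peak lognormal intensity CV
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least two subjects")
        if not (0 <= self.spot_cv < 1):
            raise ValueError("spot intensity CV must be in [0, 1)")
        if any(abs(r) >= 1 for r in self.correlation_targets.values()):
            raise ValueError("correlation targets must satisfy |r| < 1")


@dataclass(frozen=True)
class GroundTruth:
    """True per-subject abundances and traits, plus the parameters used."""

    abundances: pd.DataFrame          # subjects x glycans, rows sum to 100
    traits: pd.DataFrame              # subjects x 16 traits
    dispersions: Dict[str, float]     # tuned logistic-normal sigma per group
    fitted_means: Dict[str, pd.Series]


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    library: Dict[str, GlycanAnnotation]
    metadata: pd.DataFrame            # sample_id, group, stage, set, CA125, HE4
    truth: GroundTruth
    peaklists: List[PeakList]


# ---------------------------------------------------------------------------
# step 1: group mean vectors from trait targets

def _partition_cells(library: Mapping[str, GlycanAnnotation]) -> Dict[str, List[str]]:
    cells: Dict[str, List[str]] = {
        "man": [], "s1": [], "s2": [], "s3": [], "s4": [], "g0": [], "g1": [], "g2": [], "rest": []
    }
    for key, ann in library.items():
        c = ann.composition
        if ann.glycan_class == "oligomannose":
            cells["man"].append(key)
        elif c.neu5ac >= 1:
            cells[f"s{min(c.neu5ac, 4)}"].append(key)
        elif ann.glycan_class == "complex":
            cells[f"g{min(ann.galactoses, 2)}"].append(key)
        else:
            cells["rest"].append(key)
    return cells


def _overlap_groups(library: Mapping[str, GlycanAnnotation]) -> Dict[str, List[str]]:
    groups: Dict[str, List[str]] = {"f_neutral": [], "f_sialo": [], "b_neutral": [], "b_sialo": []}
    for key, ann in library.items():
        c = ann.composition
        if c.dhex >= 1:
            groups["f_sialo" if c.neu5ac else "f_neutral"].append(key)
        if ann.bisected:
            groups["b_sialo" if c.neu5ac else "b_neutral"].append(key)
    return groups


def _validate_targets(t: Mapping[str, Tuple[float, float]]) -> List[str]:
    mean = {k: v[0] for k, v in t.items()}
    problems = []
    for name, lhs, rhs in (
        ("s_total = s1+s2+s3+s4", mean["s_total"], mean["s1"] + mean["s2"] + mean["s3"] + mean["s4"]),
        ("g_total = g1+g2", mean["g_total"], mean["g1"] + mean["g2"]),
        ("f_total = f_neutral+f_sialo", mean["f_total"], mean["f_neutral"] + mean["f_sialo"]),
        ("b_total = b_neutral+b_sialo", mean["b_total"], mean["b_neutral"] + mean["b_sialo"]),
    ):
        if abs(lhs - rhs) > 0.2:
            problems.append(f"additivity violated: {name} ({lhs:.2f} vs {rhs:.2f})")
    partition = mean["man"] + mean["s_total"] + mean["g0"] + mean["g1"] + mean["g2"]
    if partition > 100 + 1e-9:
        problems.append(f"Man + S total + G0 + G1 + G2 = {partition:.2f} exceeds 100")
    if any(v < 0 or v > 100 for v in mean.values()):
        problems.append("trait means must lie in [0, 100]")
    return problems


def calibrate_group_means(
    trait_targets: Mapping[str, Tuple[float, float]],
    library: Mapping[str, GlycanAnnotation],
    tol: float = 1e-9,
    max_sweeps: int = 500,
) -> Tuple[pd.Series, Dict[str, float]]:
    """Per-glycan mean abundance vector reproducing the trait targets.

    Starts from a uniform spread within each disjoint structural cell
    (oligomannose, S1-S4, neutral complex by galactose count, remainder) and
    iteratively rescales each constrained trait group to its target and its
    complement to 100 minus the target (iterative proportional fitting over
    overlapping constraints), renormalizing implicitly at every step.
    Returns the fitted vector and the residual per constraint.  Raises on
    internally inconsistent or infeasible targets, listing the violations.
    """
    problems = _validate_targets(trait_targets)
    if problems:
        raise ValueError("infeasible trait targets: " + "; ".join(problems))
    mean = {k: v[0] for k, v in trait_targets.items()}
    cells = _partition_cells(library)
    rest_mass = 100.0 - (mean["man"] + mean["s1"] + mean["s2"] + mean["s3"] + mean["s4"]
                         + mean["g0"] + mean["g1"] + mean["g2"])
    cell_targets = {**{k: mean[k] for k in ("man", "s1", "s2", "s3", "s4", "g0", "g1", "g2")},
                    "rest": rest_mass}
    for cell, keys in cells.items():
        if cell_targets[cell] > 1e-9 and not keys:
            raise ValueError(f"infeasible trait targets: no library glycan supports cell {cell!r}")

    keys = sorted(library)
    index = {k: i for i, k in enumerate(keys)}
    a = np.zeros(len(keys))
    for cell, members in cells.items():
        if members:
            for k in members:
                a[index[k]] = cell_targets[cell] / len(members)

    constraints: Dict[str, Tuple[np.ndarray, float]] = {}
    for cell, members in cells.items():
        mask = np.zeros(len(keys), dtype=bool)
        mask[[index[k] for k in members]] = True
        constraints[cell] = (mask, cell_targets[cell])
    for name, members in _overlap_groups(library).items():
        mask = np.zeros(len(keys), dtype=bool)
        mask[[index[k] for k in members]] = True
        constraints[name] = (mask, mean[name])

    residuals = {}
    for _ in range(max_sweeps):
        worst = 0.0
        for name, (mask, target) in constraints.items():
            cur = a[mask].sum()
            worst = max(worst, abs(cur - target))
            if cur > 0 and 0 < target < 100:
                a[mask] *= target / cur
                other = a[~mask].sum()
                if other > 0:
                    a[~mask] *= (100.0 - target) / other
        if worst < tol:
            break
    for name, (mask, target) in constraints.items():
        residuals[name] = float(a[mask].sum() - target)
    if max(abs(r) for r in residuals.values()) > 1e-6:
        raise ValueError(
            "infeasible trait targets: iterative fitting did not converge; residuals "
            + ", ".join(f"{k}={v:.2e}" for k, v in sorted(residuals.items()) if abs(v) > 1e-6)
        )
    return pd.Series(a, index=keys), residuals


# ---------------------------------------------------------------------------
# step 2: subjects around the group mean

def _s_total_sd(abund: np.ndarray, sialo_mask: np.ndarray) -> float:
    return float(abund[:, sialo_mask].sum(axis=1).std(ddof=1))


def _logistic_normal(mean_vec: np.ndarray, z: np.ndarray, sigma: float) -> np.ndarray:
    latent = np.log(np.maximum(mean_vec, 1e-12))[None, :] + sigma * z
    expl = np.exp(latent - latent.max(axis=1, keepdims=True))
    return 100.0 * expl / expl.sum(axis=1, keepdims=True)


def _centered_logistic_normal(mean_vec: np.ndarray, z: np.ndarray, sigma: float) -> np.ndarray:
    """Logistic-normal draw whose realized column means equal ``mean_vec``.

    The closure-then-renormalize transform is nonlinear, so perturbing
    log(mean) directly would bias the cohort mean away from the calibrated
    vector (Jensen's inequality).  A fixed-point correction of the latent
    baseline removes that bias: the sampled group reproduces the calibrated
    per-glycan means (hence the targeted trait means, which are linear)
    essentially exactly.
    """
    base = mean_vec.copy()
    for _ in range(200):
        a = _logistic_normal(base, z, sigma)
        cur = a.mean(axis=0)
        if np.max(np.abs(cur - mean_vec)) < 1e-12:
            break
        base *= mean_vec / np.maximum(cur, 1e-300)
    return a


def sample_subjects(
    spec: CohortSpec,
    fitted_means: Mapping[str, pd.Series],
    library: Mapping[str, GlycanAnnotation],
    subject_groups: Sequence[Tuple[str, str]],
    rng: np.random.Generator,
) -> GroundTruth:
    """Draw per-subject abundance vectors around each group's fitted mean.

    ``subject_groups`` is a sequence of (sample_id, target_group) pairs where
    target_group keys into ``fitted_means``.  Perturbations are
    logistic-normal with one dispersion sigma per group, found by bisection
    so the across-subject SD of the total-sialylation trait matches its
    target; the latent Gaussian residuals are centred within each group so
    the realized cohort means sit on the calibrated values rather than a
    sampling offset away from them.
    """
    keys = list(next(iter(fitted_means.values())).index)
    sialo_mask = np.array([library[k].composition.neu5ac > 0 for k in keys])
    rows = []
    dispersions: Dict[str, float] = {}
    ids: List[str] = []
    by_group: Dict[str, List[str]] = {}
    for sid, grp in subject_groups:
        by_group.setdefault(grp, []).append(sid)
    frames = {}
    for grp, members in by_group.items():
        mean_vec = fitted_means[grp].reindex(keys).to_numpy()
        sd_target = spec.trait_targets[grp]["s_total"][1]
        n = len(members)
        z = rng.standard_normal((n, len(keys)))
        z -= z.mean(axis=0, keepdims=True)
        lo, hi = 0.0, 2.0
        while _s_total_sd(_centered_logistic_normal(mean_vec, z, hi), sialo_mask) < sd_target and hi < 32:
            hi *= 2
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _s_total_sd(_centered_logistic_normal(mean_vec, z, mid), sialo_mask) < sd_target:
                lo = mid
            else:
                hi = mid
        sigma = 0.5 * (lo + hi)
        dispersions[grp] = sigma
        frames[grp] = pd.DataFrame(_centered_logistic_normal(mean_vec, z, sigma), index=members, columns=keys)
    for sid, grp in subject_groups:
        rows.append(frames[grp].loc[sid])
        ids.append(sid)
    abund = pd.DataFrame(rows, index=ids)
    trait_profiles = [
        compute_traits(GlycanProfile(sid, dict(zip(keys, abund.loc[sid]))), library)
        for sid in ids
    ]
    return GroundTruth(
        abundances=abund,
        traits=traits_to_frame(trait_profiles),
        dispersions=dispersions,
        fitted_means={g: s.copy() for g, s in fitted_means.items()},
    )


# ---------------------------------------------------------------------------
# step 3: measurement layer

def emit_peaklists(
    abundances: pd.DataFrame,
    mass_cfg: MassConfig,
    spec: CohortSpec,
    library: Mapping[str, GlycanAnnotation],
    rng: np.random.Generator,
) -> List[PeakList]:
    """Triplicate MALDI-style peak lists for every subject.

    The mass-error model mimics reflector-TOF behaviour: every spot carries
    a coherent calibration scale error (``mz_jitter_ppm``, shared by all
    peaks of the spot and removable by internal recalibration) plus
    independent per-peak centroiding noise (``centroid_jitter_ppm``).
    Intensity = true abundance x per-peak lognormal factor (CV
    ``spot_cv``); ``noise_peaks`` uniform-m/z noise peaks with intensities
    up to ``noise_intensity`` (on the same scale as the abundances) are
    appended.
    """
    keys = list(abundances.columns)
    theo = np.array([theoretical_mz(library[k].composition, mass_cfg) for k in keys])
    ln_sigma = np.sqrt(np.log(1.0 + spec.spot_cv**2)) if spec.spot_cv > 0 else 0.0
    out: List[PeakList] = []
    for sid in abundances.index:
        base = abundances.loc[sid].to_numpy()
        for rep in range(1, spec.replicates + 1):
            spot_delta = spec.mz_jitter_ppm * 1e-6 * rng.standard_normal()
            jitter = theo * spot_delta + theo * spec.centroid_jitter_ppm * 1e-6 * rng.standard_normal(len(theo))
            if ln_sigma > 0:
                factors = rng.lognormal(mean=-0.5 * ln_sigma**2, sigma=ln_sigma, size=len(theo))
            else:
                factors = np.ones(len(theo))
            mz = theo + jitter
            inten = base * factors
            if spec.noise_peaks > 0:
                mz = np.concatenate([mz, rng.uniform(1000.0, 4500.0, spec.noise_peaks)])
                inten = np.concatenate([inten, rng.uniform(0.0, spec.noise_intensity, spec.noise_peaks)])
            out.append(PeakList(sid, rep, mz, inten))
    return out


def emit_covariates(
    true_traits: pd.DataFrame,
    groups: pd.Series,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """CA125 and HE4 covariates for every subject.

    For the combined benign + cancer subjects CA125 is a linear combination
    of the targeted traits plus noise, with coefficients solved from the
    empirical trait correlation matrix (and the noise component orthogonal-
    ized against the traits) so each marginal Pearson correlation matches
    its target; healthy controls receive independent baseline values.  HE4
    is drawn independently of the glycome with a benign-below-cancer group
    shift.  Raises when the requested joint correlations are not attainable
    (non-positive residual variance).
    """
    idx = true_traits.index
    diseased = groups.isin(["benign", "cancer"]).to_numpy()
    targets = dict(spec.correlation_targets)
    trait_names = list(targets)
    rho = np.array([targets[t] for t in trait_names])

    ca125 = np.empty(len(idx))
    T = true_traits.loc[diseased, trait_names].to_numpy()
    n = T.shape[0]
    Tz = (T - T.mean(axis=0)) / T.std(axis=0)
    R = (Tz.T @ Tz) / n
    w = np.linalg.solve(R, rho)
    resid_var = 1.0 - float(rho @ w)
    if resid_var <= 0:
        raise ValueError("unattainable joint correlation targets (residual variance <= 0)")
    eps = rng.standard_normal(n)
    # orthogonalize the noise against the traits so the empirical (not just
    # expected) correlations hit their targets
    design = np.column_stack([np.ones(n), Tz])
    eps = eps - design @ np.linalg.lstsq(design, eps, rcond=None)[0]
    sd = eps.std()
    eps = eps / sd if sd > 0 else eps
    z = Tz @ w + np.sqrt(resid_var) * eps
    ca125[diseased] = 150.0 + 120.0 * z
    ca125[~diseased] = rng.normal(15.0, 5.0, int((~diseased).sum()))

    he4 = np.empty(len(idx))
    loc = {"normal": (45.0, 10.0), "benign": (55.0, 15.0), "cancer": (90.0, 30.0)}
    for grp, (mu, sd_g) in loc.items():
        mask = (groups == grp).to_numpy()
        he4[mask] = rng.normal(mu, sd_g, int(mask.sum()))
    return pd.DataFrame({"CA125": ca125, "HE4": he4}, index=idx)


# ---------------------------------------------------------------------------
# orchestration

def _subject_table(spec: CohortSpec) -> pd.DataFrame:
    rows = []
    prefixes = {"normal": "N", "benign": "B", "cancer": "C"}
    stages_early, stages_late = ("I", "II"), ("III", "IV")
    for grp, n in spec.group_sizes.items():
        for i in range(n):
            sid = f"{prefixes.get(grp, grp[0].upper())}{i + 1:03d}"
            if grp == "cancer":
                early = i < (n + 1) // 2
                stage = (stages_early if early else stages_late)[i % 2]
                target = "early" if early else "late"
            else:
                stage, target = "none", grp
            rows.append({"sample_id": sid, "group": grp, "stage": stage, "target_group": target})
    df = pd.DataFrame(rows)
    # explicit discovery/validation split: first ~60% of each group by id
    df["set"] = "validation"
    for grp in spec.group_sizes:
        members = df.index[df["group"] == grp]
        df.loc[members[: int(np.ceil(0.6 * len(members)))], "set"] = "discovery"
    return df


def generate_cohort(
    spec: CohortSpec,
    library: Mapping[str, GlycanAnnotation] | None = None,
    mass_cfg: MassConfig = MassConfig(),
) -> SyntheticCohort:
    """Full cohort: metadata, ground truth, peak lists and covariates."""
    lib = dict(library if library is not None else default_library())
    subjects = _subject_table(spec)
    fitted = {}
    for grp in sorted(set(subjects["target_group"])):
        fitted[grp], _ = calibrate_group_means(spec.trait_targets[grp], lib)
    master = np.random.default_rng(spec.seed)
    rng_subjects, rng_peaks, rng_cov = master.spawn(3)
    truth = sample_subjects(
        spec, fitted, lib, list(zip(subjects["sample_id"], subjects["target_group"])), rng_subjects
    )
    peaklists = emit_peaklists(truth.abundances, mass_cfg, spec, lib, rng_peaks)
    cov = emit_covariates(
        truth.traits, subjects.set_index("sample_id")["group"].reindex(truth.traits.index), spec, rng_cov
    )
    meta = subjects.drop(columns=["target_group"]).set_index("sample_id").join(cov).reset_index()
    return SyntheticCohort(spec=spec, library=lib, metadata=meta, truth=truth, peaklists=peaklists)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write the cohort in the pipeline's input layout.

    ``peaks/{sample}_{replicate}.csv``, ``metadata.tsv``, ``library.tsv``
    plus ground-truth abundance and trait tables.
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    for pl in cohort.peaklists:
        write_peaklist_csv(pl, outdir / "peaks" / f"{pl.sample_id}_{pl.replicate}.csv")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_library(cohort.library, outdir / "library.tsv")
    cohort.truth.abundances.to_csv(outdir / "ground_truth_abundances.tsv", sep="\t")
    cohort.truth.traits.to_csv(outdir / "ground_truth_traits.tsv", sep="\t")
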