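"""Synthetic mixed-gamble choice data and metabolic volumes with planted effects.

Every downstream stage of the package (behavioral inference, voxelwise
GLM, moderation) can be exercised against ground truth produced here:
gamble designs, choices simulated from known gain/loss weights, cohorts
with known per-subject loss aversion, and aligned 3-D "metabolism"
volumes carrying planted group, coupling and sex-interaction clusters.

All generators are pure functions of their seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import VolumeImage

__all__ = [
    "GroundTruthEffects",
    "generate_gamble_design",
    "simulate_choices",
    "lambda_to_betas",
    "generate_cohort",
    "generate_pet_reference",
    "generate_metabolic_volumes",
    "default_affine",
    "ellipsoid_mask",
]

# Study-condition defaults: cohort composition and per-group loss-aversion
# distributions (behavioral sample 22 AUD / 19 HC, imaging reference 42).
DEFAULT_N_AUD = 22
DEFAULT_N_HC = 19
DEFAULT_N_PET_HC = 42
DEFAULT_SEX_COUNTS = {"AUD": 9, "HC": 8}  # females per group
DEFAULT_LAMBDA_SPECS = {"AUD": (1.90, 0.23), "HC": (2.13, 0.38)}
# Logit weight per AU of gain; sets choice stochasticity.  At 104 trials
# this scale gives lambda-estimate reliability ~0.85, i.e. measured lambda
# SDs close to the latent group SDs, as in consistently-choosing subjects.
DEFAULT_BETA_GAIN = 0.25
DEFAULT_INTERCEPT = 0.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# gamble design and choices
# ---------------------------------------------------------------------------

def generate_gamble_design(
    n_trials: int = 104,
    value_range: tuple[float, float] = (1, 99),
    max_abs_corr: float = 0.10,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 1000,
) -> pd.DataFrame:
    """Draw a mixed-gamble trial set: gains and losses symmetric in a range.

    Gains and losses are integers drawn uniformly on ``value_range`` with
    rejection sampling until the |Pearson correlation| between gain and
    loss columns does not exceed ``max_abs_corr``.  A constant column
    makes the correlation undefined; it is treated as 0.

    Returns a DataFrame with columns ``trial``, ``gain``, ``loss``,
    ``win_probability`` (fixed at 0.5); losses are stored as positive
    magnitudes.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    lo, hi = value_range
    if lo <= 0 or hi < lo:
        raise ValueError("value_range must be positive with lo <= hi")
    if not (0 <= max_abs_corr < 1):
        raise ValueError("max_abs_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    lo_i, hi_i = int(np.ceil(lo)), int(np.floor(hi))
    for _ in range(max_attempts):
        gain = rng.integers(lo_i, hi_i + 1, size=n_trials)
        loss = rng.integers(lo_i, hi_i + 1, size=n_trials)
        if gain.std() == 0 or loss.std() == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(gain, loss)[0, 1])
        if abs(corr) <= max_abs_corr:
            return pd.DataFrame(
                {
                    "trial": np.arange(n_trials),
                    "gain": gain.astype(float),
                    "loss": loss.astype(float),
                    "win_probability": 0.5,
                }
            )
    raise RuntimeError(
        f"could not satisfy |corr| <= {max_abs_corr} in {max_attempts} attempts"
    )


def simulate_choices(
    design: pd.DataFrame,
    beta_gain: float,
    beta_loss: float,
    intercept: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate accept/reject decisions from the logistic value model.

    P(accept) = logistic(intercept + beta_gain * G - beta_loss * L);
    both weights are positive, the loss weight enters with negative sign,
    so the implied loss aversion is lambda = beta_loss / beta_gain.
    """
    for name, v in [("beta_gain", beta_gain), ("beta_loss", beta_loss),
                    ("intercept", intercept)]:
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if beta_gain <= 0 or beta_loss <= 0:
        raise ValueError("beta_gain and beta_loss must be positive")
    rng = np.random.default_rng(seed)
    eta = np.clip(intercept + beta_gain * design["gain"].to_numpy()
                  - beta_loss * design["loss"].to_numpy(), -700, 700)
    p_accept = 1.0 / (1.0 + np.exp(-eta))
    out = design.copy()
    out["accept"] = (rng.random(len(design)) < p_accept).astype(int)
    return out


def lambda_to_betas(lam: float, beta_gain: float = DEFAULT_BETA_GAIN
                    ) -> tuple[float, float]:
    """Map a loss-aversion value to (beta_gain, beta_loss).

    lambda only constrains the ratio of the two weights; the gain-weight
    scale controls how noisy the simulated choices are.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return beta_gain, lam * beta_gain


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lower, size):
    """Draw by resampling below the lower bound; sd=0 returns the mean."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if mean <= lower:
        raise ValueError(f"truncation bound {lower} excludes the mean {mean}")
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise RuntimeError("truncated-normal resampling did not converge")


def generate_cohort(
    n_aud: int = DEFAULT_N_AUD,
    n_hc: int = DEFAULT_N_HC,
    sex_counts: dict[str, int] | None = None,
    lambda_specs: dict[str, tuple[float, float]] | None = None,
    beta_gain: float = DEFAULT_BETA_GAIN,
    intercept: float = DEFAULT_INTERCEPT,
    n_trials: int = 104,
    lambda_floor: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate the behavioral cohort: covariates, true lambda, choices.

    Each subject's true loss aversion is drawn from their group's normal
    distribution (truncated below at ``lambda_floor``), converted to
    logit weights via :func:`lambda_to_betas`, and used to simulate a
    fresh gamble design and 104-trial choice set.

    Returns ``(subjects, choices)`` where ``subjects`` is one row per
    subject and ``choices`` maps subject_id to its trial table.
    """
    if n_aud < 1 or n_hc < 1:
        raise ValueError("group counts must be positive")
    sex_counts = dict(DEFAULT_SEX_COUNTS if sex_counts is None else sex_counts)
    lambda_specs = dict(DEFAULT_LAMBDA_SPECS if lambda_specs is None else lambda_specs)
    rng = np.random.default_rng(seed)

    rows, choices = [], {}
    for group, n in [("AUD", n_aud), ("HC", n_hc)]:
        mean, sd = lambda_specs[group]
        lams = _truncated_normal(rng, mean, sd, lambda_floor, n)
        n_f = sex_counts.get(group, n // 2)
        n_f = int(round(n_f * n / (DEFAULT_N_AUD if group == "AUD" else DEFAULT_N_HC))) \
            if n != (DEFAULT_N_AUD if group == "AUD" else DEFAULT_N_HC) else n_f
        n_f = min(n_f, n)
        sexes = np.array(["female"] * n_f + ["male"] * (n - n_f))
        for i in range(n):
            sid = f"{group.lower()}{i + 1:03d}"
            lam = float(lams[i])
            bg, bl = lambda_to_betas(lam, beta_gain)
            design = generate_gamble_design(n_trials=n_trials, seed=rng)
            choices[sid] = simulate_choices(design, bg, bl, intercept, seed=rng)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "sex": sexes[i],
                    "age": float(np.clip(rng.normal(47, 9), 25, 65)),
                    "education": float(np.clip(rng.normal(12, 3), 5, 20)),
                    "smoking": int(rng.random() < (0.6 if group == "AUD" else 0.3)),
                    "risk_score": float(rng.normal(0, 1)),
                    "disease_duration": float(np.clip(rng.normal(10.40, 6.43), 1, 26))
                    if group == "AUD" else np.nan,
                    "bmi": float(np.clip(rng.normal(24.5, 3.0), 17, 35)),
                    "nutrition_score": int(rng.integers(0, 4)),
                    "sleep_score": int(rng.integers(0, 4)),
                    "anxiety_score": int(rng.integers(0, 4)),
                    "true_lambda": lam,
                    "true_beta_gain": bg,
                    "true_beta_loss": bl,
                    "true_intercept": intercept,
                }
            )
    return pd.DataFrame(rows), choices


def generate_pet_reference(
    n: int = DEFAULT_N_PET_HC,
    n_female: int | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Covariates for the imaging-only reference group (age/sex matched).

    These subjects carry no behavioral data; only age and sex are known,
    mirroring an external normative PET database.
    """
    rng = np.random.default_rng(seed)
    if n_female is None:
        n_female = int(round(n * 17 / 42))
    sexes = np.array(["female"] * n_female + ["male"] * (n - n_female))
    return pd.DataFrame(
        {
            "subject_id": [f"pethc{i + 1:03d}" for i in range(n)],
            "group": "PET-HC",
            "sex": sexes,
            "age": np.clip(rng.normal(47, 9, n), 25, 65),
        }
    )


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def default_affine(shape: tuple[int, int, int], voxel_mm: float = 4.0
                   ) -> np.ndarray:
    """RAS+ affine placing the world origin at the grid center."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return aff


def ellipsoid_mask(shape: tuple[int, int, int],
                   semiaxes_frac: tuple[float, float, float] = (0.42, 0.44, 0.42)
                   ) -> np.ndarray:
    """Ellipsoidal stand-in for a brain mask, centered in the grid."""
    grids = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(semiaxes_frac) * np.asarray(shape)
    d2 = sum(((grids[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def _sphere(shape, center_frac, radius_frac) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    center = np.asarray(center_frac) * (np.asarray(shape) - 1)
    r = radius_frac * min(shape)
    d2 = sum((grids[a] - center[a]) ** 2 for a in range(3))
    return d2 <= r ** 2


@dataclass
class GroundTruthEffects:
    """Planted spatial effects for the synthetic metabolism volumes.

    Amplitudes are in raw intensity units on a baseline of ``baseline``;
    coupling slopes are intensity units per unit of (centered) loss
    aversion. ``noise_sd`` is the in-mask standard deviation of the
    smoothed noise field, i.e. the residual scale the voxelwise GLM sees.
    """

    brain_mask: np.ndarray
    group_hypo_mask: np.ndarray
    group_hyper_mask: np.ndarray
    la_mask: np.ndarray
    interaction_mask: np.ndarray
    group_hypo_amp: float = -8.0
    group_hyper_amp: float = 8.0
    la_slope: float = -45.0
    interaction_slope_male: float = -150.0
    interaction_slope_female: float = 0.0
    # per-subject lambda-independent metabolic variability inside the
    # interaction region (both sexes): real regional metabolism varies
    # between subjects for reasons other than loss aversion, and without
    # this the no-coupling sex has near-zero ROI variance, making its
    # simple slope in the (inverse) moderation regression ill-conditioned
    interaction_regional_sd: float = 10.0
    age_slope: float = -0.10  # global age effect, units per year
    noise_sd: float = 4.0
    fwhm_mm: float = 8.0
    baseline: float = 100.0

    def __post_init__(self) -> None:
        named = {
            "group_hypo_mask": self.group_hypo_mask,
            "group_hyper_mask": self.group_hyper_mask,
            "la_mask": self.la_mask,
            "interaction_mask": self.interaction_mask,
        }
        for name, m in named.items():
            if not m.any():
                raise ValueError(f"{name} is empty")
            if m.shape != self.brain_mask.shape:
                raise ValueError(f"{name} shape mismatch with brain mask")
            if (m & ~self.brain_mask).any():
                raise ValueError(f"{name} extends outside the brain mask")

    @classmethod
    def default(cls, shape: tuple[int, int, int] = (40, 48, 40), **kw
                ) -> "GroundTruthEffects":
        """Planted geometry scaled to any grid shape.

        The loss-aversion coupling sphere overlaps the group
        hypometabolism sphere so the conjunction analysis has a nonempty
        true intersection; the sex-interaction sphere sits elsewhere.
        """
        brain = ellipsoid_mask(shape)
        hypo = _sphere(shape, (0.51, 0.67, 0.64), 0.095) & brain
        la = _sphere(shape, (0.44, 0.64, 0.62), 0.095) & brain
        hyper = _sphere(shape, (0.50, 0.30, 0.55), 0.075) & brain
        inter = _sphere(shape, (0.58, 0.40, 0.70), 0.100) & brain
        return cls(brain, hypo, hyper, la, inter, **kw)


def generate_metabolic_volumes(
    subjects: pd.DataFrame,
    effects: GroundTruthEffects,
    affine: np.ndarray | None = None,
    voxel_mm: float = 4.0,
    global_factor_sd: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> dict[str, VolumeImage]:
    """Per-subject volumes = baseline + planted effects + smoothed noise.

    The loss-aversion used for coupling terms is the subject's true
    lambda, centered across subjects that have one (imaging-only
    controls contribute no coupling signal).  A per-subject lognormal
    global factor emulates uptake variability and is removed downstream
    by proportional scaling.
    """
    rng = np.random.default_rng(seed)
    shape = effects.brain_mask.shape
    if affine is None:
        affine = default_affine(shape, voxel_mm)
    sigma_vox = effects.fwhm_mm * FWHM_TO_SIGMA / np.sqrt(
        (np.asarray(affine)[:3, :3] ** 2).sum(axis=0))

    lam = subjects.get("true_lambda")
    if lam is None:
        lam_c = np.zeros(len(subjects))
    else:
        lam = lam.to_numpy(dtype=float)
        have = np.isfinite(lam)
        lam_c = np.where(have, lam - (lam[have].mean() if have.any() else 0.0), 0.0)
    age = subjects["age"].to_numpy(dtype=float)
    age_c = age - age.mean()

    vols: dict[str, VolumeImage] = {}
    for i, row in enumerate(subjects.itertuples(index=False)):
        img = np.zeros(shape)
        img[effects.brain_mask] = effects.baseline
        if row.group == "AUD":
            img[effects.group_hypo_mask] += effects.group_hypo_amp
            img[effects.group_hyper_mask] += effects.group_hyper_amp
        img[effects.la_mask] += effects.la_slope * lam_c[i]
        sex_slope = (effects.interaction_slope_female if row.sex == "female"
                     else effects.interaction_slope_male)
        img[effects.interaction_mask] += sex_slope * lam_c[i]
        img[effects.interaction_mask] += rng.normal(
            0.0, effects.interaction_regional_sd)
        img[effects.brain_mask] += effects.age_slope * age_c[i]

        noise = gaussian_filter(rng.standard_normal(shape), sigma_vox,
                                mode="reflect")
        sd = noise[effects.brain_mask].std()
        img[effects.brain_mask] += (effects.noise_sd / sd) * noise[effects.brain_mask]
        if global_factor_sd > 0:
            img *= float(np.exp(rng.normal(0.0, global_factor_sd)))
        vols[row.subject_id] = VolumeImage(img, affine, mask=effects.brain_mask)
    return vols
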