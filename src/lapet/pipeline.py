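"""End-to-end orchestration: synthetic data -> behavior -> voxelwise GLM -> moderation.

A single :class:`RunConfig` drives the full analysis chain from one
top-level seed: generate (or load) choice data and metabolism volumes,
estimate per-subject loss aversion and run the behavioral battery,
compute the voxelwise contrasts (group hypo/hyper-metabolism with age
nuisance; loss-aversion regression and sex-by-LA interaction in the
patient sample; conjunction of the group and coupling maps), extract
the interaction-cluster ROI, and fit the sex-moderation model on the
ROI means.  Every stochastic step draws its substream from the single
seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, moderation, petglm, synthetic
from .volume import VolumeImage

__all__ = ["RunConfig", "RunReport", "run_pipeline", "dice"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)


@dataclass
class RunConfig:
    """Pipeline configuration.  Serializes losslessly to/from YAML."""

    seed: int = 0
    out_dir: str | None = None
    save_nifti: bool = False
    # synthetic-generation block (None values fall back to module defaults)
    n_aud: int = 22
    n_hc: int = 19
    n_pet_hc: int = 42
    n_trials: int = 104
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_mm: float = 4.0
    effects: dict = field(default_factory=dict)   # GroundTruthEffects overrides
    global_factor_sd: float = 0.10
    # behavioral options; the synthetic generator plants no acceptance
    # bias, so the matched estimator omits the intercept — set True when
    # analyzing real choice data that may carry one
    include_intercept: bool = False
    welch: bool = False
    # voxel options
    fwhm_mm: float = 8.0
    forming_p: float = 0.001
    q_fdr: float = 0.05
    n_permutations: int = 1000
    connectivity: int = 18
    # moderation options
    hc_type: str = "HC3"
    bootstrap_B: int = 5000
    alpha: float = 0.05

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Structured result of a full pipeline run."""

    config_digest: str
    seed: int
    flags: dict
    behavioral: pd.DataFrame
    lambda_table: pd.DataFrame
    cluster_tables: dict
    conjunction_table: pd.DataFrame
    moderation_summary: dict
    truth_scores: dict
    roi_means: pd.Series | None = None

    def to_json(self) -> str:
        payload = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "flags": self.flags,
            "behavioral": self.behavioral.to_dict(orient="records"),
            "lambda_table": self.lambda_table.round(10).to_dict(orient="records"),
            "cluster_tables": {k: v.to_dict(orient="records")
                               for k, v in self.cluster_tables.items()},
            "conjunction": self.conjunction_table.to_dict(orient="records"),
            "moderation": self.moderation_summary,
            "truth_scores": self.truth_scores,
            "roi_means": (self.roi_means.round(12).to_dict()
                          if self.roi_means is not None else None),
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=float)


def _moderation_summary(res: moderation.ModerationResult,
                        jn: moderation.JNResult) -> dict:
    coef = res.coefficients
    eff = moderation.effect_sizes(delta_r2=max(res.delta_r2, 0.0),
                                  r2_full=res.r2)
    power = moderation.posthoc_power(eff["cohen_f2"], 1, res.df2, n=res.n,
                                     alpha=res.alpha, ncp_convention="both")
    out = {
        "n": res.n, "r2": res.r2, "mse": res.mse,
        "f_robust": res.f_robust, "f_classical": res.f_classical,
        "df1": res.df1, "df2": res.df2, "p_model": res.p_model,
        "delta_r2": res.delta_r2,
        "f_interaction_robust": res.f_interaction_robust,
        "p_interaction_robust": res.p_interaction_robust,
        "coefficients": coef.round(12).to_dict(orient="index"),
        "conditional_effects": res.conditional_effects.round(12)
                                  .to_dict(orient="records"),
        "effect_sizes": eff,
        "posthoc_power": power,
        "johnson_neyman": {"boundaries": jn.boundaries, "region": jn.region,
                           "code": jn.code},
    }
    if res.bootstrap is not None:
        out["bootstrap"] = res.bootstrap.round(12).to_dict(orient="index")
        out["bootstrap_B"] = res.bootstrap_B
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis chain on synthetic data.

    Stage order: cohort + choice generation, volume generation,
    loss-aversion estimation and behavioral tests, SUVR scaling and
    smoothing, the four voxelwise analyses, ROI extraction from the
    sex-by-LA interaction cluster, and the moderation model.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_cohort, s_pet, s_vol, s_perm_g, s_perm_la, s_perm_int,
     s_boot) = [np.random.Generator(np.random.PCG64(c))
                for c in ss.spawn(7)]

    # --- stage 1: synthetic cohort and volumes -------------------------
    try:
        subjects, choices = synthetic.generate_cohort(
            n_aud=config.n_aud, n_hc=config.n_hc, n_trials=config.n_trials,
            seed=s_cohort)
        pet_ref = synthetic.generate_pet_reference(n=config.n_pet_hc,
                                                   seed=s_pet)
        effects = synthetic.GroundTruthEffects.default(
            tuple(config.grid_shape), **config.effects)
        imaging = pd.concat(
            [subjects[subjects["group"] == "AUD"], pet_ref],
            ignore_index=True)
        volumes = synthetic.generate_metabolic_volumes(
            imaging, effects, voxel_mm=config.voxel_mm,
            global_factor_sd=config.global_factor_sd, seed=s_vol)
    except Exception as e:
        raise RuntimeError(f"stage synthetic_data failed: {e}") from e

    # --- stage 2: behavior ---------------------------------------------
    try:
        lam_rows = []
        for sid in subjects["subject_id"]:
            est = behavior.estimate_lambda(
                choices[sid], include_intercept=config.include_intercept)
            lam_rows.append({"subject_id": sid, "lambda": est.lambda_,
                             "beta_gain": est.beta_gain,
                             "beta_loss": est.beta_loss,
                             "separation_flag": est.separation_flag})
        lam_tab = subjects.merge(pd.DataFrame(lam_rows), on="subject_id")
        lam_tab["lambda_resid"] = behavior.residualize_lambda(
            lam_tab["lambda"], lam_tab["risk_score"])

        tests = []
        t = behavior.two_sample_test(lam_tab["lambda_resid"],
                                     lam_tab["group"], welch=config.welch)
        t.family = "group"
        tests.append(t)
        cov = lam_tab[["age", "education", "smoking"]]
        a = behavior.ancova_group_effect(lam_tab["lambda_resid"],
                                         lam_tab["group"], cov)
        a.family = "group"
        tests.append(a)
        for term, res in behavior.factorial_anova_2x2(
                lam_tab["lambda_resid"], lam_tab["group"],
                lam_tab["sex"]).items():
            res.family = "anova2x2"
            tests.append(res)
        behav_report = behavior.behavioral_report(tests)
    except Exception as e:
        raise RuntimeError(f"stage behavior_model failed: {e}") from e

    # --- stage 3: voxelwise GLM ----------------------------------------
    try:
        suvr = {sid: petglm.smooth_gaussian(
                    petglm.proportional_scale(v), config.fwhm_mm)
                for sid, v in volumes.items()}
        aud = lam_tab[lam_tab["group"] == "AUD"].reset_index(drop=True)
        sex_code = aud["sex"].map(moderation.DEFAULT_SEX_CODING).to_numpy()
        aud_vols = [suvr[s] for s in aud["subject_id"]]

        im_ids = list(imaging["subject_id"])
        group_ind = (imaging["group"] == "AUD").to_numpy(float)
        d_group = petglm.DesignSpec.build(
            {"group": group_ind, "age": imaging["age"].to_numpy(float)},
            contrast={"group": 1.0}, contrast_name="AUD_vs_HC",
            direction=-1)  # hypometabolism: AUD lower
        map_hypo = petglm.fit_voxelwise_glm([suvr[s] for s in im_ids], d_group)
        cl_hypo = petglm.cluster_inference(
            map_hypo, config.forming_p, config.q_fdr, config.n_permutations,
            config.connectivity, seed=s_perm_g)
        map_hyper = petglm.fit_voxelwise_glm(
            [suvr[s] for s in im_ids],
            d_group.with_contrast({"group": 1.0}, "AUD_gt_HC", direction=1))
        cl_hyper = petglm.cluster_inference(
            map_hyper, config.forming_p, config.q_fdr,
            config.n_permutations, config.connectivity, seed=s_perm_g)

        d_la = petglm.DesignSpec.build(
            {"la": aud["lambda_resid"].to_numpy(),
             "duration": aud["disease_duration"].to_numpy(float)},
            contrast={"la": 1.0}, contrast_name="LA_negative_coupling",
            direction=-1)
        map_la = petglm.fit_voxelwise_glm(aud_vols, d_la)
        cl_la = petglm.cluster_inference(
            map_la, config.forming_p, config.q_fdr, config.n_permutations,
            config.connectivity, seed=s_perm_la)

        d_int = petglm.DesignSpec.build(
            {"la": aud["lambda_resid"].to_numpy(), "sex": sex_code},
            contrast={"sex_x_la": 1.0}, contrast_name="sex_x_LA",
            direction=1, center=("la",), products={"sex_x_la": ("sex", "la")})
        map_int = petglm.fit_voxelwise_glm(aud_vols, d_int)
        cl_int = petglm.cluster_inference(
            map_int, config.forming_p, config.q_fdr, config.n_permutations,
            config.connectivity, seed=s_perm_int)

        conj_map, conj_tab = petglm.conjunction(
            map_hypo, map_la, config.forming_p, cl_hypo, cl_la,
            config.connectivity)
    except Exception as e:
        raise RuntimeError(f"stage pet_glm failed: {e}") from e

    # --- stage 4: moderation on the interaction-cluster ROI -------------
    try:
        roi_source = "interaction_cluster"
        sig_ids = cl_int.significant_ids()
        if sig_ids:
            roi_id = int(cl_int.table.loc[
                cl_int.table["cluster_id"].isin(sig_ids), "extent"].idxmax())
            roi_id = int(cl_int.table.loc[roi_id, "cluster_id"])
        elif len(cl_int.table):
            roi_id = int(cl_int.table.iloc[0]["cluster_id"])
            roi_source = "largest_nonsignificant_cluster"
        else:
            roi_id = None
            roi_source = "planted_truth_mask_fallback"
        if roi_id is not None:
            roi_mask = petglm.cluster_to_mask(cl_int, roi_id)
        else:
            roi_mask = VolumeImage(effects.interaction_mask.astype(float),
                                   aud_vols[0].affine,
                                   mask=effects.brain_mask)
        roi_means = petglm.extract_roi_means(
            {s: v for s, v in zip(aud["subject_id"], aud_vols)}, roi_mask)
        mod_res = moderation.fit_moderation(
            outcome=aud["lambda_resid"].to_numpy(),
            focal=roi_means.loc[aud["subject_id"]].to_numpy(),
            moderator=aud["sex"].to_numpy(),
            covariates=aud[["disease_duration"]],
            hc_type=config.hc_type, alpha=config.alpha,
            B=config.bootstrap_B,
            seed=int(s_boot.integers(0, 2**31 - 1)))
        jn = moderation.johnson_neyman(mod_res)
    except Exception as e:
        raise RuntimeError(f"stage moderation failed: {e}") from e

    # --- scoring against planted truth ----------------------------------
    sig_union = np.isin(cl_hypo.label_map, cl_hypo.significant_ids())
    sig_la = np.isin(cl_la.label_map, cl_la.significant_ids())
    sig_int = np.isin(cl_int.label_map, cl_int.significant_ids())
    truth_scores = {
        "dice_group_hypo": dice(sig_union, effects.group_hypo_mask),
        "dice_la_coupling": dice(sig_la, effects.la_mask),
        "dice_interaction": dice(sig_int, effects.interaction_mask),
        "conjunction_inside_truth_intersection": bool(
            conj_map.any()
            and (conj_map & ~(effects.group_hypo_mask
                              | effects.la_mask)).sum() == 0),
    }

    b3 = mod_res.coefficient("interaction")
    truth_b3_positive = (effects.interaction_slope_male
                         < effects.interaction_slope_female)
    aud_mean = lam_tab.loc[lam_tab["group"] == "AUD", "lambda_resid"].mean()
    hc_mean = lam_tab.loc[lam_tab["group"] == "HC", "lambda_resid"].mean()
    flags = {
        "group_lambda_difference_detected": bool(
            behav_report.loc[behav_report["test"] == "two_sample_t",
                             "p"].iloc[0] < 0.05 and aud_mean < hc_mean),
        "hypometabolism_cluster_found": cl_hypo.n_significant > 0,
        "hypermetabolism_cluster_found": cl_hyper.n_significant > 0,
        "la_coupling_cluster_found": cl_la.n_significant > 0,
        "conjunction_nonempty": bool(conj_map.any()),
        "interaction_cluster_found": cl_int.n_significant > 0,
        "moderation_b3_sign_matches_truth": bool((b3 > 0) == truth_b3_positive),
        "roi_source": roi_source,
    }

    report = RunReport(
        config_digest=config.digest(), seed=config.seed, flags=flags,
        behavioral=behav_report, lambda_table=lam_tab,
        cluster_tables={"group_hypo": cl_hypo.table,
                        "group_hyper": cl_hyper.table,
                        "la_coupling": cl_la.table,
                        "interaction": cl_int.table},
        conjunction_table=conj_tab,
        moderation_summary=_moderation_summary(mod_res, jn),
        truth_scores=truth_scores,
        roi_means=roi_means,
    )

    if config.out_dir is not None:
        _write_outputs(config, report, lam_tab, choices,
                       {"hypo": map_hypo, "hyper": map_hyper,
                        "la": map_la, "interaction": map_int},
                       roi_mask, conj_map)
    return report


def _write_outputs(config, report, lam_tab, choices, maps, roi_mask,
                   conj_map) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    lam_tab.to_csv(out / "subjects_lambda.tsv", sep="\t", index=False)
    report.behavioral.to_csv(out / "behavioral_tests.tsv", sep="\t",
                             index=False)
    for name, tab in report.cluster_tables.items():
        tab.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
    report.conjunction_table.to_csv(out / "clusters_conjunction.tsv",
                                    sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "files": sorted(p.name for p in out.iterdir())}
    if config.save_nifti:
        import nibabel as nib
        for name, m in maps.items():
            VolumeImage(np.nan_to_num(m.data), m.affine).save(
                out / f"tmap_{name}.nii.gz")
        roi_mask.save(out / "roi_interaction_mask.nii.gz")
        VolumeImage(conj_map.astype(float), roi_mask.affine).save(
            out / "conjunction_mask.nii.gz")
        manifest["files"] = sorted(p.name for p in out.iterdir())
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
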