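"""Recovery report: re-estimate every generating parameter from a
simulated study and compare it with its configured value.

Each check row carries the estimate, the target, the tolerance used
(3 standard errors of the relevant kind: Monte-Carlo over replicates for
heritabilities, regression for covariate effects, binomial for rates,
Fisher for correlations) and a pass flag.  Heritability, covariate and
environmental-correlation checks need the latent (pre-medication /
component) outputs, which a debug run retains.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimation
from .config import StudyConfig
from .study import PhenotypeReplicate, Study

__all__ = ["validate_study", "validate_run"]


def _check(name, estimate, target, tol):
    return {
        "check": name,
        "estimate": estimate,
        "target": target,
        "tolerance": tol,
        "pass": bool(abs(estimate - target) <= tol) if np.isfinite(estimate) else False,
    }


def validate_study(
    study: Study,
    replicates: list[PhenotypeReplicate],
    null_scan_alpha: float | None = None,
) -> pd.DataFrame:
    """Run all parameter-recovery checks on in-memory replicates."""
    cfg = study.config
    ids = study.phenotyped_ids
    A = study.relationship_phenotyped
    X = study.covariate_design(exam=1)
    rows = []

    # heritability of exam-1 raw pressures, per replicate then averaged
    for trait, target in (("sbp", cfg.h2_sbp), ("dbp", cfg.h2_dbp)):
        Y = np.column_stack([r.latent[f"raw_{trait}_e1"].to_numpy() for r in replicates])
        fits = estimation.estimate_heritability_many(Y, X, A)
        est = np.array([f.h2_estimate for f in fits])
        mcse = est.std(ddof=1) / np.sqrt(len(est))
        rows.append(_check(f"h2_{trait}_exam1", est.mean(), target, 3 * mcse))

    # Q1 heritability
    Yq = np.column_stack([r.q1.to_numpy() for r in replicates])
    fits = estimation.estimate_heritability_many(Yq, X, A)
    est = np.array([f.h2_estimate for f in fits])
    mcse = est.std(ddof=1) / np.sqrt(len(est))
    rows.append(_check("h2_q1", est.mean(), cfg.q1.h2, 3 * mcse))

    # covariate effects from pooled raw exam-1 values
    families = np.array([study.pedigrees[p].family_id for p in ids])
    pooled = pd.concat(
        [
            pd.DataFrame(
                {
                    "sex": study.sexes.reindex(ids).to_numpy(),
                    "age": study.schedule["age_exam1"].reindex(ids).to_numpy(),
                    "family": families,
                    "sbp": r.latent["raw_sbp_e1"].to_numpy(),
                    "dbp": r.latent["raw_dbp_e1"].to_numpy(),
                }
            )
            for r in replicates
        ],
        ignore_index=True,
    )
    cov = cfg.covariates
    targets = {
        ("sbp", "female_offset"): cov.female_offset_sbp,
        ("sbp", "age_slope_male"): cov.age_slope_sbp_male,
        ("sbp", "age_slope_female"): cov.age_slope_sbp_female,
        ("dbp", "female_offset"): cov.female_offset_dbp,
        ("dbp", "age_slope_male"): cov.age_slope_dbp_male,
        ("dbp", "age_slope_female"): cov.age_slope_dbp_female,
    }
    for trait in ("sbp", "dbp"):
        tab = estimation.recover_covariate_effects(
            pooled, trait, age_center=cov.age_center, cluster=pooled["family"]
        )
        for coef in ("female_offset", "age_slope_male", "age_slope_female"):
            rows.append(
                _check(
                    f"{coef}_{trait}",
                    tab.loc[coef, "estimate"],
                    targets[(trait, coef)],
                    3 * tab.loc[coef, "se"],
                )
            )

    # treatment and smoking rates
    phen_all = pd.concat([r.phenotypes for r in replicates], ignore_index=True)
    rates = estimation.estimate_rates(phen_all)
    for e in (1, 2, 3):
        rows.append(
            _check(
                f"treated_fraction_exam{e}",
                rates.loc[e, "treated_fraction"],
                cfg.treatment.treat_prob_by_exam[e - 1],
                3 * rates.loc[e, "treated_se"],
            )
        )
    rows.append(
        _check(
            "smoker_fraction_exam1",
            rates.loc[1, "smoker_fraction"],
            cfg.treatment.smoker_init,
            3 * rates.loc[1, "smoker_se"],
        )
    )

    # environmental correlations, pooled over replicates
    from .traits import ENV_COMPONENTS

    env_all = pd.concat(
        [r.latent[list(ENV_COMPONENTS)] for r in replicates], ignore_index=True
    )
    emp = estimation.estimate_env_correlations(env_all).to_numpy()
    target_corr = np.asarray(cfg.env_corr, dtype=float)
    n_eff = len(env_all)
    iu = np.triu_indices(6, k=1)
    err = np.abs(emp[iu] - target_corr[iu])
    se = (1 - target_corr[iu] ** 2) / np.sqrt(n_eff)
    rows.append(
        {
            "check": "env_corr_max_abs_error",
            "estimate": float(err.max()),
            "target": 0.0,
            "tolerance": float(3 * se.max()),
            "pass": bool((err <= 3 * se).all()),
        }
    )

    # optional null association scan of Q1
    if null_scan_alpha is not None:
        rep = replicates[0]
        rngs = study.replicate_rngs(rep.replicate)
        from . import effects, genotypes

        background = effects.build_background_set(
            study.background_candidates, cfg.n_background, seed=rngs["background"]
        )
        back = genotypes.drop_genotypes(
            study.pedigrees, list(background.variants), seed=rngs["backgeno"]
        )
        dos = pd.concat([study.fixed_dosages, back], axis=1).loc[ids]
        rate = estimation.null_scan(rep.q1, dos, X, A, alpha=null_scan_alpha)
        m = dos.shape[1]
        tol = 3 * np.sqrt(null_scan_alpha * (1 - null_scan_alpha) / m)
        rows.append(_check("q1_null_rejection_rate", rate, null_scan_alpha, tol))

    return pd.DataFrame(rows).set_index("check")


def validate_run(out_dir, null_scan_alpha: float | None = None) -> pd.DataFrame:
    """Validate an on-disk study: rebuild the study deterministically from
    the manifest configuration and read the replicate files back."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    config = StudyConfig.from_dict(manifest["config"])
    study = Study(config)
    replicates = []
    for r in range(1, manifest["n_replicates"] + 1):
        latent_path = out / f"latent_r{r:03d}.tsv"
        if not latent_path.exists():
            raise FileNotFoundError(
                f"{latent_path} missing: validation needs a debug run (config.debug=true)"
            )
        replicates.append(
            PhenotypeReplicate(
                replicate=r,
                phenotypes=pd.read_csv(out / f"phenotypes_r{r:03d}.tsv", sep="\t"),
                q1=pd.read_csv(out / f"q1_r{r:03d}.tsv", sep="\t", index_col="person_id")["q1"],
                latent=pd.read_csv(latent_path, sep="\t", index_col="person_id"),
            )
        )
    return validate_study(study, replicates, null_scan_alpha=null_scan_alpha)
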