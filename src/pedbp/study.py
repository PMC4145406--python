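"""Replicate orchestration: wire pedigrees, genotypes, effects, traits and
treatment into whole simulated studies.

A :class:`Study` fixes everything that is constant across replicates
(pedigree structure, sex, exam ages, functional/interaction genotypes,
the phenotyped subsample, the relationship matrix) from the base seed,
then generates each replicate's stochastic layers (background variant
set and genotypes, environmental components, treatment, smoking, Q1)
from a counter-based per-replicate seed, so any replicate can be
reproduced independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effects, genotypes, pedigree, traits, treatment
from .config import StudyConfig

__all__ = ["Study", "PhenotypeReplicate", "run_study"]

_STUDY_TAG = 0x5EDB  # domain separator for study-level seeding
_REP_TAG = 0x4E9C  # domain separator for replicate-level seeding


@dataclass
class PhenotypeReplicate:
    """One replicate of the simulated study.

    ``phenotypes`` is long format (person_id, exam, age, sex, sbp, dbp,
    htn, meds, smoke) holding observed (post-medication) pressures;
    ``q1`` is the exam-1-only null trait; ``latent`` retains the genetic
    values, environmental components and pre-medication pressures for
    validation.
    """

    replicate: int
    phenotypes: pd.DataFrame
    q1: pd.Series
    latent: pd.DataFrame


class Study:
    def __init__(self, config: StudyConfig | None = None):
        self.config = config or StudyConfig()
        cfg = self.config
        root = np.random.SeedSequence([_STUDY_TAG, int(cfg.base_seed)])
        (s_ped, s_ages, s_geno, s_sub, s_cand) = [
            np.random.default_rng(s) for s in root.spawn(5)
        ]
        self.pedigrees = pedigree.generate_pedigree_set(
            cfg.n_families,
            cfg.family_size_range,
            cfg.n_mz_pairs,
            seed=int(s_ped.integers(2**31)),
        )
        self.relationship = pedigree.additive_relationship(self.pedigrees)
        self.sexes = pd.Series(
            {i.person_id: i.sex for i in self.pedigrees.individuals}, name="sex"
        ).reindex(self.pedigrees.person_ids)
        self.schedule = self._make_schedule(s_ages)
        # fixed genotypes at functional + interaction variants
        self.functional = effects.load_functional_catalog()
        self.interaction = effects.load_interaction_catalog()
        fixed_variants = [f.variant for f in self.functional] + [
            i.variant for i in self.interaction
        ]
        self.fixed_dosages = genotypes.drop_genotypes(self.pedigrees, fixed_variants, seed=s_geno)
        self.background_candidates = effects.make_background_candidates(
            cfg.n_background_candidates, seed=s_cand
        )
        # phenotyped subsample, fixed across replicates
        ids = np.array(self.pedigrees.person_ids)
        if cfg.n_individuals and cfg.n_individuals < len(ids):
            keep = np.sort(s_sub.choice(len(ids), size=cfg.n_individuals, replace=False))
            self.phenotyped_ids = list(ids[keep])
        else:
            self.phenotyped_ids = list(ids)
        self.relationship_phenotyped = self.relationship.loc[
            self.phenotyped_ids, self.phenotyped_ids
        ]
        self._a_sqrt = traits.relationship_matrix_sqrt(self.relationship)
        # eigen machinery reused by the per-replicate heritability calibration
        from . import estimation

        X = np.column_stack([np.ones(len(self.phenotyped_ids)), self.covariate_design(1)])
        s_eig, U = np.linalg.eigh(self.relationship_phenotyped.to_numpy())
        self._calib = {"s": np.clip(s_eig, 0.0, None), "U": U, "Xt": U.T @ X}

    # -- study-level helpers ------------------------------------------------

    def _make_schedule(self, rng: np.random.Generator) -> pd.DataFrame:
        """Exam-1 ages by generation depth (older founders, younger
        descendants), later exams at the fixed 3.9/6.9-year gaps."""
        depth = self.pedigrees.generation_depth()
        ids = self.pedigrees.person_ids
        d = np.array([depth[p] for p in ids], dtype=float)
        age1 = np.maximum(16.0, 74.0 - 21.0 * d + rng.normal(0.0, 5.0, size=len(ids)))
        sched = pd.DataFrame(
            {"age_exam1": age1, "age_exam2": np.nan, "age_exam3": np.nan},
            index=pd.Index(ids, name="person_id"),
        )
        return traits.fill_ages(sched)

    def covariate_design(self, exam: int = 1) -> np.ndarray:
        """Fixed-effect design (female, male age, female age; centered)
        for the phenotyped subsample — what REML conditions on."""
        cfg = self.config
        female = (self.sexes.reindex(self.phenotyped_ids) == "female").to_numpy(dtype=float)
        age = self.schedule[f"age_exam{exam}"].reindex(self.phenotyped_ids).to_numpy()
        age_c = age - cfg.covariates.age_center
        return np.column_stack([female, age_c * (1 - female), age_c * female])

    # -- replicates ---------------------------------------------------------

    def replicate_rngs(self, r: int) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence([_REP_TAG, int(self.config.base_seed), int(r)])
        names = ("background", "backgeno", "env", "q1", "treat", "smoke")
        return dict(zip(names, (np.random.default_rng(s) for s in ss.spawn(len(names)))))

    def run_replicate(self, r: int) -> PhenotypeReplicate:
        cfg = self.config
        rngs = self.replicate_rngs(r)
        # replicate-specific polygenic background
        background = effects.build_background_set(
            self.background_candidates, cfg.n_background, seed=rngs["background"]
        )
        back_dos = genotypes.drop_genotypes(
            self.pedigrees, list(background.variants), seed=rngs["backgeno"]
        )
        dosages = pd.concat([self.fixed_dosages, back_dos], axis=1)
        catalog = effects.EffectCatalog(
            functional=self.functional, interaction=self.interaction, background=background
        )
        ids = self.phenotyped_ids
        dos_ph = dosages.loc[ids]
        g = pd.DataFrame(
            {
                "g_sbp": effects.genetic_value(dos_ph, catalog, "sbp"),
                "g_dbp": effects.genetic_value(dos_ph, catalog, "dbp"),
            }
        )
        # heritability-fixing environmental calibration against the REML
        # objective, from the realized genetic vector of this replicate
        from . import estimation

        cal = self._calib
        env_corr = traits.EnvCorrelation(
            corr=np.asarray(cfg.env_corr, dtype=float),
            var_sbp=estimation.calibrate_env_variance_reml(
                g["g_sbp"].to_numpy(), None, None, cfg.h2_sbp,
                _transformed=(cal["U"].T @ g["g_sbp"].to_numpy(), cal["Xt"], cal["s"]),
            ),
            var_dbp=estimation.calibrate_env_variance_reml(
                g["g_dbp"].to_numpy(), None, None, cfg.h2_dbp,
                _transformed=(cal["U"].T @ g["g_dbp"].to_numpy(), cal["Xt"], cal["s"]),
            ),
        )
        env = traits.simulate_environment(len(ids), env_corr, seed=rngs["env"])
        env.index = pd.Index(ids, name="person_id")
        sched = self.schedule.loc[ids]
        sexes = self.sexes.reindex(ids)
        raw = traits.assemble_traits(g, sched, sexes, env, cfg.covariates)
        # treatment dynamics on raw pressures
        tp = cfg.treatment
        inter_keys = [i.variant.key for i in self.interaction]
        nonresp = treatment.is_nonresponder(
            dos_ph[inter_keys].to_numpy(), cutoff=tp.carrier_dosage_cutoff
        )
        treated = {}
        prev = np.zeros(len(ids), dtype=bool)
        for e in (1, 2, 3):
            htn_now = treatment.diagnose_hypertension(
                raw[f"sbp_e{e}"], raw[f"dbp_e{e}"], prev, tp
            )
            prev = treatment.assign_medication(e, htn_now, prev, tp, seed=rngs["treat"])
            treated[f"e{e}"] = prev
        treated = pd.DataFrame(treated, index=raw.index)
        raw_sbp = raw[["sbp_e1", "sbp_e2", "sbp_e3"]].set_axis(["e1", "e2", "e3"], axis=1)
        raw_dbp = raw[["dbp_e1", "dbp_e2", "dbp_e3"]].set_axis(["e1", "e2", "e3"], axis=1)
        htn = treatment.persist_diagnosis(raw_sbp, raw_dbp, treated, tp)
        smoke = treatment.simulate_smoking(len(ids), tp, seed=rngs["smoke"])
        q1 = traits.simulate_q1(
            self.pedigrees,
            self.relationship,
            self.schedule["age_exam1"],
            cfg.q1,
            seed=rngs["q1"],
            relationship_sqrt=self._a_sqrt,
        ).reindex(ids)
        # assemble long-format observed phenotypes
        rows = []
        for e in (1, 2, 3):
            obs_sbp, obs_dbp = treatment.apply_medication(
                raw_sbp[f"e{e}"], raw_dbp[f"e{e}"], treated[f"e{e}"], nonresp, tp
            )
            rows.append(
                pd.DataFrame(
                    {
                        "person_id": ids,
                        "exam": e,
                        "age": sched[f"age_exam{e}"].to_numpy(),
                        "sex": sexes.to_numpy(),
                        "sbp": obs_sbp,
                        "dbp": obs_dbp,
                        "htn": htn[f"e{e}"].to_numpy().astype(int),
                        "meds": treated[f"e{e}"].to_numpy().astype(int),
                        "smoke": smoke[:, e - 1].astype(int),
                    }
                )
            )
        phen = pd.concat(rows, ignore_index=True)
        latent = pd.concat(
            [
                g,
                env,
                raw_sbp.add_prefix("raw_sbp_"),
                raw_dbp.add_prefix("raw_dbp_"),
            ],
            axis=1,
        )
        return PhenotypeReplicate(replicate=r, phenotypes=phen, q1=q1, latent=latent)

    def run_replicates(self, n: int | None = None, start: int = 1):
        n = n if n is not None else self.config.n_replicates
        for r in range(start, start + n):
            yield self.run_replicate(r)


def run_study(config: StudyConfig, out_dir=None, progress=None, resume: bool = True) -> dict:
    """Run the full study and write per-replicate files plus a manifest.

    Writes pedigree (PED), fixed-variant dosages (TSV) and genotypes
    (VCF) once, then ``phenotypes_r###.tsv`` and ``q1_r###.tsv`` per
    replicate (``latent_r###.tsv`` as well when ``config.debug``).
    Replicates are seeded independently, so with ``resume`` an
    interrupted run skips replicates whose files are already present.
    Returns the manifest dict.
    """
    from pathlib import Path

    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = Study(config)
    pedigree.write_pedigree(study.pedigrees, out / "pedigree.ped")
    genotypes.write_dosage_table(study.fixed_dosages, out / "dosages.tsv")
    fixed_variants = [f.variant for f in study.functional] + [
        i.variant for i in study.interaction
    ]
    genotypes.write_vcf(study.fixed_dosages, fixed_variants, out / "genotypes.vcf")
    files = []
    for r in range(1, config.n_replicates + 1):
        pf = out / f"phenotypes_r{r:03d}.tsv"
        qf = out / f"q1_r{r:03d}.tsv"
        lf = out / f"latent_r{r:03d}.tsv"
        wanted = [pf, qf] + ([lf] if config.debug else [])
        if not (resume and all(p.exists() for p in wanted)):
            rep = study.run_replicate(r)
            rep.phenotypes.to_csv(pf, sep="\t", index=False, float_format="%.6g")
            rep.q1.rename_axis("person_id").to_frame().to_csv(qf, sep="\t", float_format="%.6g")
            if config.debug:
                rep.latent.rename_axis("person_id").to_csv(lf, sep="\t", float_format="%.6g")
        files.extend(p.name for p in wanted)
        if progress is not None:
            progress(r)
    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "base_seed": config.base_seed,
        "n_replicates": config.n_replicates,
        "n_phenotyped": len(study.phenotyped_ids),
        "replicate_files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
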