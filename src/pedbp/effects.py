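"""Functional-variant effect catalog, polygenic background, and
heritability calibration.

The simulated traits are systolic and diastolic blood pressure (SBP,
DBP).  Three classes of variants carry genetic effects:

* **functional variants** — deleterious coding (and cis-regulatory)
  variants in genes whose expression tracks blood pressure; each has a
  signed per-minor-allele effect (beta, mmHg) on one or both traits.
  The packaged catalog holds the 55 largest-effect coding variants with
  their published betas and minor allele frequencies.
* **background variants** — 1000 common variants (MAF > 0.4) with a tiny
  equal-magnitude effect each (0.11187 mmHg SBP, 0.08786 mmHg DBP per
  minor allele), half positive and half negative, redrawn every
  replicate.  They supply the polygenic heritability the functional
  catalog does not.
* **interaction variants** — deleterious CYP3A43 coding variants whose
  carriers do not respond to antihypertensive medication (handled in
  :mod:`pedbp.treatment`).

For new catalogs, the coding effect-size generator is
``percentile(PP2S) * PP2S^2 * |rho_g| * k * l`` where PP2S is the
PolyPhen-2 damage score, rho_g the transcript-trait genetic correlation,
and k (global) and l (per-gene) are scaling constants.  The sign comes
from a separate direction rule: a deleterious coding variant lowers
function, so it moves the trait *against* the transcript-trait
correlation.

Total heritability is fixed by construction: the environmental variance
for each trait is calibrated per replicate from the realized genetic
variance as ``Ve = Vg (1 - h2) / h2``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .genotypes import VariantDef

__all__ = [
    "FunctionalVariant",
    "InteractionVariant",
    "BackgroundSet",
    "EffectCatalog",
    "coding_effect_magnitude",
    "effect_direction",
    "load_functional_catalog",
    "load_interaction_catalog",
    "make_background_candidates",
    "build_background_set",
    "genetic_value",
    "calibrate_environment",
    "variance_explained",
]

BACKGROUND_EFFECT_SBP = 0.11187  # mmHg per minor allele
BACKGROUND_EFFECT_DBP = 0.08786

_FIXTURE_SHA256 = {
    "functional_variants.tsv": "dc6314af33a5a37f8c4e3ee2dda6c8ca36089d6af8a8fd281cb73321124feebf",
    "cyp3a43_variants.tsv": "0d61af6786a3e43c56ce4ad724a68194f961d99ec46216c46e3c341fac70bf24",
}


@dataclass(frozen=True)
class FunctionalVariant:
    """A variant with direct signed effects on SBP and/or DBP."""

    variant: VariantDef
    beta_dbp: float = 0.0  # mmHg per minor allele, signed
    beta_sbp: float = 0.0
    pp2s: float | None = None  # PolyPhen-2 score, coding variants
    rho_g_dbp: float | None = None
    rho_g_sbp: float | None = None

    def __post_init__(self):
        if self.beta_dbp == 0.0 and self.beta_sbp == 0.0:
            raise ValueError(f"{self.variant.key}: at least one beta must be nonzero")
        if self.pp2s is not None and not (0.0 <= self.pp2s <= 1.0):
            raise ValueError("pp2s must be in [0, 1]")

    def beta(self, trait: str) -> float:
        return self.beta_sbp if trait == "sbp" else self.beta_dbp


@dataclass(frozen=True)
class InteractionVariant:
    """A deleterious CYP3A43 coding variant defining medication nonresponse."""

    variant: VariantDef
    polyphen_score: float

    def __post_init__(self):
        if not (0.0 <= self.polyphen_score <= 1.0):
            raise ValueError("polyphen_score must be in [0, 1]")


@dataclass(frozen=True)
class BackgroundSet:
    """The per-replicate polygenic background: common variants with
    equal-magnitude, half-positive/half-negative effects."""

    variants: tuple[VariantDef, ...]
    signs: tuple[int, ...]
    magnitude_sbp: float = BACKGROUND_EFFECT_SBP
    magnitude_dbp: float = BACKGROUND_EFFECT_DBP

    def __post_init__(self):
        if len(self.signs) != len(self.variants):
            raise ValueError("signs and variants must align")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +/-1")
        n_pos = sum(1 for s in self.signs if s > 0)
        if 2 * n_pos != len(self.signs):
            raise ValueError("exactly half of the signs must be positive")
        if any(v.maf <= 0.4 for v in self.variants):
            raise ValueError("background variants must have maf > 0.4")

    def betas(self, trait: str) -> np.ndarray:
        mag = self.magnitude_sbp if trait == "sbp" else self.magnitude_dbp
        return mag * np.asarray(self.signs, dtype=float)


@dataclass
class EffectCatalog:
    """All variants entering the genetic model, with scaling constants."""

    functional: list[FunctionalVariant]
    interaction: list[InteractionVariant] = field(default_factory=list)
    background: BackgroundSet | None = None
    k: float = 1.0
    l_by_gene: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        keys = [f.variant.key for f in self.functional]
        keys += [i.variant.key for i in self.interaction]
        if self.background is not None:
            keys += [v.key for v in self.background.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("variant keys must be unique across the catalog")

    def all_variants(self) -> list[VariantDef]:
        out = [f.variant for f in self.functional] + [i.variant for i in self.interaction]
        if self.background is not None:
            out += list(self.background.variants)
        return out


# ---------------------------------------------------------------------------
# Effect-size generator


def coding_effect_magnitude(
    pp2s: float, pp2s_percentile: float, rho_g: float, k: float = 1.0, l: float = 1.0
) -> float:
    """Unsigned coding-variant effect size:
    ``percentile(PP2S) * PP2S^2 * |rho_g| * k * l``.

    The sign is supplied separately by :func:`effect_direction`.
    """
    if not (0.0 <= pp2s <= 1.0):
        raise ValueError("pp2s must be in [0, 1]")
    if not (0.0 <= pp2s_percentile <= 1.0):
        raise ValueError("pp2s_percentile must be in [0, 1]")
    if not (-1.0 <= rho_g <= 1.0):
        raise ValueError("rho_g must be in [-1, 1]")
    if k <= 0 or l <= 0:
        raise ValueError("k and l must be positive")
    return pp2s_percentile * pp2s**2 * abs(rho_g) * k * l


def effect_direction(mrna_trait_correlation_sign: int, category: str) -> int:
    """Sign of a variant's trait effect.

    Deleterious coding variants reduce gene function, so their effect
    opposes the transcript-trait correlation; regulatory variants follow
    the observed correlation direction.
    """
    if mrna_trait_correlation_sign not in (-1, 1):
        raise ValueError("correlation sign must be +1 or -1 (zero has no direction)")
    if category == "coding":
        return -mrna_trait_correlation_sign
    if category == "regulatory":
        return mrna_trait_correlation_sign
    raise ValueError(f"no direction rule for category {category!r}")


# ---------------------------------------------------------------------------
# Packaged catalog fixtures


def _fixture_path(name: str):
    path = resources.files("pedbp.data").joinpath(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} is corrupted (sha256 mismatch)")
    return path


def load_functional_catalog(path=None) -> list[FunctionalVariant]:
    """Load the packaged 55-variant functional catalog (or a user table
    in the same tab-separated dialect)."""
    src = _fixture_path("functional_variants.tsv") if path is None else path
    with resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        v = VariantDef(
            chromosome=str(row.chromosome),
            position=int(row.position),
            maf=float(row.maf),
            gene=str(row.gene),
            category="coding",
        )
        out.append(
            FunctionalVariant(variant=v, beta_dbp=float(row.beta_dbp), beta_sbp=float(row.beta_sbp))
        )
    return out


def _noop(x):
    import contextlib

    return contextlib.nullcontext(x)


def load_interaction_catalog(path=None) -> list[InteractionVariant]:
    """Load the CYP3A43 medication-nonresponse variants."""
    src = _fixture_path("cyp3a43_variants.tsv") if path is None else path
    with resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        v = VariantDef(
            chromosome=str(row.chromosome),
            position=int(row.position),
            maf=float(row.maf),
            gene="CYP3A43",
            category="coding",
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
        )
        out.append(InteractionVariant(variant=v, polyphen_score=float(row.polyphen_score)))
    return out


def load_variance_explained_table(path=None) -> pd.DataFrame:
    """The published per-variant variance-explained percentages, for
    approximate cross-checks ("<0.01" parsed as 0.01)."""
    src = _fixture_path("functional_variants.tsv") if path is None else path
    with resources.as_file(src) if path is None else _noop(src) as p:
        df = pd.read_csv(p, sep="\t")
    for col in ("ve_dbp_pct", "ve_sbp_pct"):
        df[col] = df[col].astype(str).str.lstrip("<").astype(float)
    df["key"] = df["chromosome"].astype(str) + ":" + df["position"].astype(str)
    return df.set_index("key")


# ---------------------------------------------------------------------------
# Polygenic background


def make_background_candidates(
    n_candidates: int = 2000, seed: int | np.random.Generator = 0
) -> list[VariantDef]:
    """Synthesize a pool of common (MAF > 0.4) candidate variants on odd
    autosomes, in genes disjoint from the functional catalog."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = np.array([str(c) for c in range(1, 22, 2)])
    out = []
    seen = set()
    while len(out) < n_candidates:
        chrom = str(rng.choice(chroms))
        pos = int(rng.integers(10_000, 200_000_000))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        maf = float(rng.uniform(0.401, 0.5))
        out.append(
            VariantDef(
                chromosome=chrom,
                position=pos,
                maf=round(maf, 4),
                gene=f"BG{len(out) + 1:05d}",
                category="background",
            )
        )
    return out


def build_background_set(
    candidates: list[VariantDef], n: int = 1000, seed: int | np.random.Generator = 0
) -> BackgroundSet:
    """Sample ``n`` background variants without replacement and assign
    exactly half of them positive effect signs."""
    if n % 2:
        raise ValueError("n must be even (half positive, half negative signs)")
    if len(candidates) < n:
        raise ValueError(f"need at least {n} candidates, got {len(candidates)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    signs = np.array([1] * (n // 2) + [-1] * (n // 2))
    rng.shuffle(signs)
    return BackgroundSet(
        variants=tuple(candidates[i] for i in idx),
        signs=tuple(int(s) for s in signs),
    )


# ---------------------------------------------------------------------------
# Genetic values and calibration


def genetic_value(dosages: pd.DataFrame, catalog: EffectCatalog, trait: str) -> pd.Series:
    """Per-person additive genetic value (mmHg) for ``trait``:
    sum of dosage x signed beta over functional and background variants,
    each component centered to sample mean zero."""
    if trait not in ("sbp", "dbp"):
        raise ValueError("trait must be 'sbp' or 'dbp'")
    keys = [f.variant.key for f in catalog.functional]
    if catalog.background is not None:
        keys += [v.key for v in catalog.background.variants]
    missing = [k for k in keys if k not in dosages.columns]
    if missing:
        raise KeyError(f"dosage table lacks variant columns: {missing[:5]}")
    fk = [f.variant.key for f in catalog.functional]
    fb = np.array([f.beta(trait) for f in catalog.functional])
    g = dosages[fk].to_numpy(dtype=float) @ fb
    g = g - g.mean()
    if catalog.background is not None and len(catalog.background.variants):
        bk = [v.key for v in catalog.background.variants]
        poly = dosages[bk].to_numpy(dtype=float) @ catalog.background.betas(trait)
        g = g + (poly - poly.mean())
    return pd.Series(g, index=dosages.index, name=f"g_{trait}")


def calibrate_environment(genetic_variance: float, h2_target: float) -> float:
    """Environmental variance making the heritability exactly
    ``h2_target``: ``Ve = Vg (1 - h2) / h2``."""
    if genetic_variance <= 0:
        raise ValueError("genetic_variance must be positive")
    if not (0.0 < h2_target < 1.0):
        raise ValueError("h2_target must be in (0, 1)")
    return genetic_variance * (1.0 - h2_target) / h2_target


def variance_explained(beta: float, dosage_variance: float, total_variance: float) -> float:
    """Percent of phenotypic variance explained by one variant:
    ``100 * beta^2 * Var(dosage) / Var(trait)``."""
    if total_variance <= 0:
        raise ValueError("total_variance must be positive")
    return 100.0 * beta**2 * dosage_variance / total_variance
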