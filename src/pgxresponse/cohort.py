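"""Synthetic depression-cohort generator with known ground-truth effects.

Emulates the structure of a large patient-reported antidepressant-response
cohort: CYP2C19 tier-1 genotypes drawn under Hardy–Weinberg random mating,
adult age and sex demographics, overlapping exposure to the three
CYP2C19-metabolised SSRIs (sertraline, citalopram, escitalopram), and
per-(participant, drug) outcomes — a 3-level ordinal efficacy rating,
discontinuation due to side effects, any-side-effect and 23 named
side-effect binaries — generated from proportional-odds and logistic
models with configurable metaboliser log-odds effects and a shared
participant-level random intercept.

Defaults reproduce the marginals of the cohort the generator emulates:
haplotype frequencies 21.4% (*17), 14% (*2), 0.02% (*3); age ~
N(42.8, 15.1^2) truncated to [18, 90]; 76% female; ~69/25/6% of
participants on one/two/three drugs; drug-specific baseline outcome
rates taken from the normal-metaboliser rows of the published response
tables.  All status effects default to zero, so the generator's null is
exactly the analysis models' null.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .translation import (
    TIER1_VARIANTS,
    canonical_diplotype,
    diplotype_name,
    diplotype_to_status,
)

logger = logging.getLogger(__name__)

DRUGS: tuple[str, ...] = ("sertraline", "citalopram", "escitalopram")

#: 23 patient-reported side effects collected per drug.
SIDE_EFFECTS: tuple[str, ...] = (
    "weight_loss",
    "fatigue",
    "drowsiness",
    "nausea",
    "dry_mouth",
    "insomnia",
    "dizziness",
    "headache",
    "sweating",
    "tremor",
    "constipation",
    "diarrhoea",
    "agitation",
    "anxiety",
    "reduced_libido",
    "weight_gain",
    "blurred_vision",
    "palpitations",
    "vivid_dreams",
    "yawning",
    "restlessness",
    "appetite_loss",
    "bruxism",
)

#: Outcomes that accept status effects in ``CohortConfig.status_betas``.
OUTCOMES: tuple[str, ...] = ("efficacy", "discontinued", "any_side_effect")

# Normal-metaboliser efficacy category counts (low/moderate/well) per drug,
# used to place the default cumulative-logit thresholds.
_EFFICACY_BASELINE_COUNTS = {
    "sertraline": (851, 825, 644),
    "citalopram": (349, 376, 240),
    "escitalopram": (564, 672, 526),
}

# Normal-metaboliser event rates for the binary outcomes per drug.
_DISCONTINUATION_BASELINE = {
    "sertraline": 775 / (775 + 917),
    "citalopram": 290 / (290 + 360),
    "escitalopram": 493 / (493 + 791),
}
_ANY_SIDE_EFFECT_BASELINE = {
    "sertraline": 1683 / (1683 + 716),
    "citalopram": 656 / (656 + 356),
    "escitalopram": 1300 / (1300 + 534),
}

# Per-drug exposure counts -> Plackett–Luce selection weights.
_DRUG_EXPOSURE_COUNTS = {"sertraline": 5680, "citalopram": 2503, "escitalopram": 4342}

# GRCh37 coordinates used when writing genotypes to VCF (chrom 10); the
# caller matches by rsID so the build is informational only.
_VCF_SITES = {
    "rs12248560": ("10", 96521657, "C", "T"),
    "rs4244285": ("10", 96541616, "G", "A"),
    "rs4986893": ("10", 96540410, "G", "A"),
}


def _default_efficacy_thresholds() -> dict[str, tuple[float, float]]:
    out = {}
    for drug, (a, b, c) in _EFFICACY_BASELINE_COUNTS.items():
        total = a + b + c
        out[drug] = (float(logit(a / total)), float(logit((a + b) / total)))
    return out


def _default_drug_marginals() -> dict[str, float]:
    n_pheno = 9168
    return {d: _DRUG_EXPOSURE_COUNTS[d] / n_pheno for d in DRUGS}


@dataclass
class CohortConfig:
    """Configuration for one synthetic cohort.

    Attributes
    ----------
    n_participants
        Cohort size.
    haplotype_freqs
        Map star allele -> population haplotype frequency for *2, *3,
        *17; *1 takes the remainder.
    age_mean, age_sd
        Age distribution in years, truncated to [18, 90].
    prop_female
        Probability of female sex (coded 1).
    drug_marginals
        Per-drug exposure probabilities, used as proportional selection
        weights when choosing which drugs a participant takes.
    n_drugs_dist
        Probabilities of taking exactly 1, 2 or 3 of the SSRIs.
    efficacy_thresholds
        Per-drug cumulative-logit thresholds (theta1, theta2) for
        P(efficacy <= k) = expit(theta_k - lp); must be increasing.
    discontinuation_intercepts, any_side_effect_intercepts
        Per-drug logit-scale baselines for the binary outcomes.
    side_effect_rates
        Baseline probability per named side effect (scalar applied to
        all 23, or a per-effect map).
    status_betas
        outcome -> {status -> log-odds effect vs normal}; absent
        entries are zero.  Positive efficacy effects shift responses
        toward "very well"; positive binary effects raise event odds.
    beta_age, beta_sex
        Covariate log-odds effects shared across outcomes.
    random_intercept_sd
        SD of the participant-level random intercept shared across all
        of a participant's records and outcomes; 0 gives independent
        draws at the intercept-implied marginals.
    seed
        Default RNG seed for :func:`generate_cohort`.
    """

    n_participants: int = 9531
    haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: {"*2": 0.14, "*3": 0.0002, "*17": 0.214}
    )
    age_mean: float = 42.8
    age_sd: float = 15.1
    age_bounds: tuple[float, float] = (18.0, 90.0)
    prop_female: float = 0.76
    drug_marginals: dict[str, float] = field(default_factory=_default_drug_marginals)
    n_drugs_dist: tuple[float, float, float] = (0.69, 0.25, 0.06)
    efficacy_thresholds: dict[str, tuple[float, float]] = field(
        default_factory=_default_efficacy_thresholds
    )
    discontinuation_intercepts: dict[str, float] = field(
        default_factory=lambda: {d: float(logit(p)) for d, p in _DISCONTINUATION_BASELINE.items()}
    )
    any_side_effect_intercepts: dict[str, float] = field(
        default_factory=lambda: {d: float(logit(p)) for d, p in _ANY_SIDE_EFFECT_BASELINE.items()}
    )
    side_effect_rates: float | dict[str, float] = 0.15
    status_betas: dict[str, dict[str, float]] = field(default_factory=dict)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    random_intercept_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        freq_sum = sum(self.haplotype_freqs.values())
        if any(not 0 <= f <= 1 for f in self.haplotype_freqs.values()) or freq_sum > 1:
            raise ValueError(
                "haplotype frequencies must lie in [0, 1] and sum to <= 1 "
                f"(got sum {freq_sum})"
            )
        if abs(sum(self.n_drugs_dist) - 1.0) > 1e-9:
            raise ValueError("n_drugs_dist must sum to 1")
        for drug, (t1, t2) in self.efficacy_thresholds.items():
            if not t1 < t2:
                raise ValueError(
                    f"efficacy thresholds for {drug} must be strictly increasing"
                )
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must lie in [0, 1]")

    def status_beta(self, outcome: str, status: str) -> float:
        return self.status_betas.get(outcome, {}).get(status, 0.0)

    def side_effect_rate(self, effect: str) -> float:
        if isinstance(self.side_effect_rates, dict):
            return self.side_effect_rates.get(effect, 0.15)
        return float(self.side_effect_rates)


@dataclass
class Cohort:
    """A generated cohort: wide participant table, long outcome records, genotypes."""

    participants: pd.DataFrame  # participant_id, age, sex, diplotype, status, u
    records: pd.DataFrame  # participant_id x drug rows with outcomes
    genotypes: pd.DataFrame  # participant_id + tier-1 allele counts


def sample_genotypes(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw two haplotypes per participant and derive tier-1 allele counts.

    Returns a frame with one row per participant: ``participant_id``, the
    three rsID allele-count columns, the true ``diplotype`` and its
    ``status``.  Because genotypes are built from an explicit haplotype
    pair, the pattern is always phase-consistent: re-calling through the
    translation module round-trips and never yields indeterminate.
    """
    cfg.validate()
    n = cfg.n_participants
    freqs = cfg.haplotype_freqs
    p = np.array(
        [
            1.0 - sum(freqs.values()),
            freqs.get("*2", 0.0),
            freqs.get("*3", 0.0),
            freqs.get("*17", 0.0),
        ]
    )
    alleles = np.array(["*1", "*2", "*3", "*17"])
    draws = rng.choice(4, size=(n, 2), p=p)
    hap_a, hap_b = alleles[draws[:, 0]], alleles[draws[:, 1]]

    rows = []
    for i in range(n):
        pair = canonical_diplotype(hap_a[i], hap_b[i])
        counts = {rsid: 0 for rsid in TIER1_VARIANTS}
        for rsid, star in TIER1_VARIANTS.items():
            counts[rsid] = int(pair[0] == star) + int(pair[1] == star)
        rows.append(
            {
                "participant_id": f"P{i:06d}",
                **counts,
                "diplotype": diplotype_name(pair),
                "status": diplotype_to_status(pair),
            }
        )
    cols = ["participant_id", *TIER1_VARIANTS, "diplotype", "status"]
    return pd.DataFrame(rows, columns=cols)


def _truncnorm_loc_for_mean(
    target: float, sd: float, lo: float, hi: float
) -> float:
    """Location parameter whose [lo, hi]-truncated normal has mean ``target``.

    Truncating N(mu, sd^2) to an asymmetric window shifts its mean, so
    using the target directly as the location would bias the simulated
    ages; a one-dimensional root solve removes the bias.
    """
    from scipy.optimize import brentq

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd)) - target

    span = 4 * sd
    try:
        return float(brentq(gap, target - span, target + span, xtol=1e-8))
    except ValueError:
        return target


def sample_demographics(
    cfg: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw age (truncated normal, years) and sex (1 = female) per participant.

    The truncated-normal location is calibrated so the realized mean age
    equals ``age_mean`` despite the asymmetric [18, 90] truncation.
    """
    n = cfg.n_participants
    lo, hi = cfg.age_bounds
    if cfg.age_sd == 0:
        age = np.full(n, float(np.clip(cfg.age_mean, lo, hi)))
    else:
        loc = _truncnorm_loc_for_mean(cfg.age_mean, cfg.age_sd, lo, hi)
        a, b = (lo - loc) / cfg.age_sd, (hi - loc) / cfg.age_sd
        age = truncnorm.rvs(
            a, b, loc=loc, scale=cfg.age_sd, size=n, random_state=rng
        )
    sex = (rng.random(n) < cfg.prop_female).astype(int)
    return pd.DataFrame({"age": age, "sex": sex})


def assign_drugs(cfg: CohortConfig, rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Assign each participant 1–3 SSRIs.

    Draws the number of drugs k from ``n_drugs_dist``, then selects k
    distinct drugs with probability proportional to ``drug_marginals``
    (successive weighted sampling without replacement, implemented as
    Gumbel-top-k).
    """
    n = cfg.n_participants
    k = rng.choice([1, 2, 3], size=n, p=np.asarray(cfg.n_drugs_dist))
    w = np.array([cfg.drug_marginals[d] for d in DRUGS], dtype=float)
    if np.any(w <= 0):
        raise ValueError("drug_marginals must be positive")
    # Gumbel-top-k == Plackett–Luce sampling without replacement
    keys = np.log(w)[None, :] + rng.gumbel(size=(n, len(DRUGS)))
    order = np.argsort(-keys, axis=1)
    return [tuple(DRUGS[j] for j in sorted(order[i, : k[i]])) for i in range(n)]


def simulate_outcomes(
    cfg: CohortConfig,
    participants: pd.DataFrame,
    drug_sets: list[tuple[str, ...]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate per-(participant, drug) outcomes.

    Each participant receives a random intercept ``u ~ N(0, sigma^2)``
    shared across all their records and outcomes.  Efficacy follows the
    proportional-odds model P(y <= k) = expit(theta_k[drug] - lp) with
    lp = beta_status + beta_age*age + beta_sex*sex + u, so positive
    effects shift mass toward higher (better) categories.  Binary
    outcomes follow expit(intercept[drug] + beta_status + covariates + u).

    Returns the long-format record frame and the participant ``u`` draws.
    """
    cfg.validate()
    n = len(participants)
    sigma = cfg.random_intercept_sd
    u = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)

    age = participants["age"].to_numpy()
    sex = participants["sex"].to_numpy()
    status = participants["status"].to_numpy()
    cov = cfg.beta_age * age + cfg.beta_sex * sex

    rows = []
    for i in range(n):
        base = cov[i] + u[i]
        for drug in drug_sets[i]:
            lp_eff = cfg.status_beta("efficacy", status[i]) + base
            t1, t2 = cfg.efficacy_thresholds[drug]
            c1 = expit(t1 - lp_eff)
            c2 = expit(t2 - lp_eff)
            r = rng.random()
            efficacy = 1 if r < c1 else (2 if r < c2 else 3)

            lp_disc = (
                cfg.discontinuation_intercepts[drug]
                + cfg.status_beta("discontinued", status[i])
                + base
            )
            discontinued = int(rng.random() < expit(lp_disc))

            lp_any = (
                cfg.any_side_effect_intercepts[drug]
                + cfg.status_beta("any_side_effect", status[i])
                + base
            )
            any_se = int(rng.random() < expit(lp_any))

            se_flags = {}
            for effect in SIDE_EFFECTS:
                lp_se = (
                    float(logit(cfg.side_effect_rate(effect)))
                    + cfg.status_beta(f"se_{effect}", status[i])
                    + base
                )
                se_flags[f"se_{effect}"] = int(rng.random() < expit(lp_se))

            rows.append(
                {
                    "participant_id": participants["participant_id"].iat[i],
                    "drug": drug,
                    "status": status[i],
                    "age": age[i],
                    "sex": int(sex[i]),
                    "efficacy": efficacy,
                    "discontinued": discontinued,
                    "any_side_effect": any_se,
                    "n_side_effects": sum(se_flags.values()),
                    **se_flags,
                }
            )
    cols = [
        "participant_id",
        "drug",
        "status",
        "age",
        "sex",
        "efficacy",
        "discontinued",
        "any_side_effect",
        "n_side_effects",
        *[f"se_{e}" for e in SIDE_EFFECTS],
    ]
    return pd.DataFrame(rows, columns=cols), u


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> Cohort:
    """Generate a full cohort (genotypes, demographics, drugs, outcomes).

    Deterministic for a given config and seed; ``seed=None`` uses
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genotypes = sample_genotypes(cfg, rng)
    demo = sample_demographics(cfg, rng)
    participants = pd.concat(
        [genotypes[["participant_id"]], demo], axis=1
    )
    participants["diplotype"] = genotypes["diplotype"]
    participants["status"] = genotypes["status"]
    drug_sets = assign_drugs(cfg, rng)
    records, u = simulate_outcomes(cfg, participants, drug_sets, rng)
    participants = participants.assign(u=u)
    logger.info(
        "generate_cohort: n_participants=%d n_records=%d", len(participants), len(records)
    )
    geno_cols = ["participant_id", *TIER1_VARIANTS, "diplotype", "status"]
    return Cohort(
        participants=participants,
        records=records,
        genotypes=genotypes[geno_cols],
    )


def write_vcf(genotypes: pd.DataFrame, path: str | Path) -> Path:
    """Write tier-1 genotypes as a VCF 4.2 file with GT calls.

    Sites are identified by rsID in the ID column (GRCh37 coordinates in
    CHROM/POS for reference).
    """
    path = Path(path)
    samples = genotypes["participant_id"].tolist()
    gt_for = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxresponse-synthetic\n")
        fh.write("##contig=<ID=10>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rsid, (chrom, pos, ref, alt) in sorted(
            _VCF_SITES.items(), key=lambda kv: kv[1][1]
        ):
            counts = genotypes[rsid].tolist()
            gts = "\t".join(gt_for[int(c)] for c in counts)
            fh.write(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``out_dir``: genotypes.vcf, phenotypes.tsv, participants.tsv.

    ``phenotypes.tsv`` is long format (one row per participant x drug);
    ``participants.tsv`` is the wide per-participant table.  Output is
    byte-deterministic for a fixed cohort.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "genotypes.vcf",
        "phenotypes": out_dir / "phenotypes.tsv",
        "participants": out_dir / "participants.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    records = cohort.records.copy()
    records["age"] = records["age"].map(lambda v: f"{v:.4f}")
    records.to_csv(paths["phenotypes"], sep="\t", index=False)
    participants = cohort.participants.drop(columns=["u"]).copy()
    participants["age"] = participants["age"].map(lambda v: f"{v:.4f}")
    participants.to_csv(paths["participants"], sep="\t", index=False)
    return paths


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format phenotype table written by :func:`write_cohort`."""
    return pd.read_csv(path, sep="\t")


def config_from_dict(d: dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a (possibly partial) plain dict."""
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("n_drugs_dist", "age_bounds"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "efficacy_thresholds" in kwargs:
        kwargs["efficacy_thresholds"] = {
            k: tuple(v) for k, v in kwargs["efficacy_thresholds"].items()
        }
    cfg = CohortConfig(**kwargs)
    cfg.validate()
    return cfg
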