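"""CYP2C19 star-allele diplotype calling and metaboliser-phenotype translation.

The tier-1 *CYP2C19* panel comprises three variants, each defining one
star allele:

================  ===========  =================================
rsID              star allele  functional consequence
================  ===========  =================================
rs12248560        \\*17         increased expression (promoter)
rs4244285         \\*2          loss of function (splice defect)
rs4986893         \\*3          loss of function (premature stop)
================  ===========  =================================

``*1`` is the reference haplotype carrying none of the three variant
alleles.  A participant's diplotype (unordered pair of star alleles) is
inferred from the per-variant alternate-allele counts under the standard
no-cis assumption: a haplotype carries at most one variant-defining
allele, so e.g. a double heterozygote for rs4244285 and rs12248560 is
called ``*2/*17`` (trans).  Genotype patterns whose total variant-allele
count exceeds two admit no such haplotype pair and are returned as
indeterminate.

Diplotypes translate to the five CPIC metaboliser phenotypes (poor,
intermediate, normal, rapid, ultrarapid); the CPIC "likely intermediate"
sub-label for ``*2/*17`` and ``*3/*17`` is collapsed into intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: rsID -> star allele defined by the alternate allele at that site.
TIER1_VARIANTS: dict[str, str] = {
    "rs12248560": "*17",
    "rs4244285": "*2",
    "rs4986893": "*3",
}

#: Star alleles in canonical (numeric) order, reference first.
STAR_ALLELES: tuple[str, ...] = ("*1", "*2", "*3", "*17")

_STAR_ORDER = {a: i for i, a in enumerate(STAR_ALLELES)}

#: Metaboliser phenotype levels, slow to fast.
METABOLIZER_LEVELS: tuple[str, ...] = (
    "poor",
    "intermediate",
    "normal",
    "rapid",
    "ultrarapid",
)

INDETERMINATE = "indeterminate"

#: CPIC diplotype -> phenotype lookup for the tier-1 alleles.
DIPLOTYPE_TO_STATUS: dict[tuple[str, str], str] = {
    ("*1", "*1"): "normal",
    ("*1", "*17"): "rapid",
    ("*17", "*17"): "ultrarapid",
    ("*1", "*2"): "intermediate",
    ("*1", "*3"): "intermediate",
    ("*2", "*17"): "intermediate",
    ("*3", "*17"): "intermediate",
    ("*2", "*2"): "poor",
    ("*2", "*3"): "poor",
    ("*3", "*3"): "poor",
}


class MissingGenotypeError(ValueError):
    """A required tier-1 genotype is missing for a participant."""


def canonical_diplotype(allele_a: str, allele_b: str) -> tuple[str, str]:
    """Return the unordered star-allele pair in canonical (numeric) order.

    ``canonical_diplotype("*17", "*2") == ("*2", "*17")``.
    """
    for a in (allele_a, allele_b):
        if a not in _STAR_ORDER:
            raise ValueError(f"unknown star allele: {a!r}")
    return tuple(sorted((allele_a, allele_b), key=_STAR_ORDER.__getitem__))  # type: ignore[return-value]


def diplotype_name(diplotype: tuple[str, str]) -> str:
    """Format a diplotype pair as the conventional ``*a/*b`` string."""
    return "/".join(diplotype)


def harden_dosage(dosage: float, tolerance: float = 0.1) -> int | None:
    """Convert an imputed allele dosage (real in [0, 2]) to a hard call.

    Returns the nearest integer in {0, 1, 2} when the dosage lies within
    ``tolerance`` of it, otherwise ``None`` (missing).  The function is
    idempotent on integers and symmetric about 1:
    ``harden_dosage(2 - d) == 2 - harden_dosage(d)`` whenever both calls
    succeed.

    Parameters
    ----------
    dosage
        Imputed alternate-allele dosage, 0 <= dosage <= 2.
    tolerance
        Maximum distance from an integer for a confident call;
        0 < tolerance < 0.5.
    """
    if not 0.0 <= dosage <= 2.0:
        raise ValueError(f"dosage must lie in [0, 2], got {dosage}")
    if not 0.0 < tolerance < 0.5:
        raise ValueError(f"tolerance must lie in (0, 0.5), got {tolerance}")
    nearest = int(np.rint(dosage))
    nearest = min(max(nearest, 0), 2)
    if abs(dosage - nearest) <= tolerance:
        return nearest
    return None


def genotypes_to_diplotype(
    calls: Mapping[str, int | None],
) -> tuple[str, str] | str:
    """Infer the star-allele diplotype from tier-1 alternate-allele counts.

    Parameters
    ----------
    calls
        Map rsID -> alternate-allele count in {0, 1, 2}; all three tier-1
        rsIDs must be present and non-missing.

    Returns
    -------
    The canonical diplotype pair, or the string ``"indeterminate"`` when
    the pattern admits no phase-consistent haplotype pair (total variant
    allele count > 2, e.g. a *2 homozygote who is also a *17 carrier).

    Raises
    ------
    MissingGenotypeError
        If any tier-1 site is absent or missing; callers exclude the
        participant and account for the exclusion rather than guessing.
    """
    variant_alleles: list[str] = []
    for rsid, star in TIER1_VARIANTS.items():
        if rsid not in calls or calls[rsid] is None:
            raise MissingGenotypeError(f"missing genotype at {rsid}")
        count = calls[rsid]
        if count not in (0, 1, 2):
            raise ValueError(f"allele count at {rsid} must be 0, 1 or 2; got {count}")
        variant_alleles.extend([star] * int(count))
    unknown = set(calls) - set(TIER1_VARIANTS)
    if unknown:
        raise ValueError(f"unexpected rsIDs: {sorted(unknown)}")
    if len(variant_alleles) > 2:
        # no assignment of >2 variant alleles to two haplotypes with at
        # most one variant each
        return INDETERMINATE
    haplotypes = variant_alleles + ["*1"] * (2 - len(variant_alleles))
    return canonical_diplotype(haplotypes[0], haplotypes[1])


def diplotype_to_status(diplotype: tuple[str, str]) -> str:
    """Translate a star-allele diplotype to its CPIC metaboliser phenotype."""
    key = canonical_diplotype(*diplotype)
    return DIPLOTYPE_TO_STATUS[key]


def expected_status_frequencies(
    freq_star2: float, freq_star3: float, freq_star17: float
) -> dict[str, float]:
    """Hardy–Weinberg metaboliser-status frequencies from haplotype frequencies.

    Under random pairing of haplotypes with frequencies p1 (reference),
    p2, p3, p17 the phenotype frequencies have closed forms::

        ultrarapid   p17^2
        rapid        2 p1 p17
        normal       p1^2
        intermediate 2 (p1 + p17)(p2 + p3)
        poor         (p2 + p3)^2
    """
    p_lof = freq_star2 + freq_star3
    p1 = 1.0 - p_lof - freq_star17
    if p1 < 0:
        raise ValueError("haplotype frequencies sum to more than 1")
    return {
        "poor": p_lof**2,
        "intermediate": 2 * (p1 + freq_star17) * p_lof,
        "normal": p1**2,
        "rapid": 2 * p1 * freq_star17,
        "ultrarapid": freq_star17**2,
    }


@dataclass
class CohortCalls:
    """Result of calling metaboliser status across a cohort.

    Attributes
    ----------
    calls
        One row per successfully called sample: ``sample_id``,
        ``diplotype`` (``*a/*b`` string) and ``status``.
    excluded
        Samples that could not be called, with a ``reason`` column
        (``missing:<rsid>`` or ``indeterminate``).
    """

    calls: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )

    @property
    def n_called(self) -> int:
        return len(self.calls)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _read_vcf_counts(
    vcf_path: str,
    dosage_tolerance: float,
    prefer_dosage: bool,
    positions: Mapping[str, tuple[str, int]] | None,
) -> tuple[list[str], dict[str, list[int | None]]]:
    """Extract per-sample alternate-allele counts for the tier-1 sites."""
    from cyvcf2 import VCF

    pos_lookup: dict[tuple[str, int], str] = {}
    if positions:
        for rsid, (chrom, pos) in positions.items():
            pos_lookup[(str(chrom), int(pos))] = rsid

    vcf = VCF(vcf_path, gts012=True)
    samples = list(vcf.samples)
    counts: dict[str, list[int | None]] = {}
    for variant in vcf:
        rsid = variant.ID if variant.ID in TIER1_VARIANTS else None
        if rsid is None:
            rsid = pos_lookup.get((str(variant.CHROM), variant.POS))
        if rsid is None or rsid in counts:
            continue
        dosages = variant.format("DS") if prefer_dosage else None
        if dosages is not None:
            row: list[int | None] = []
            for d in np.asarray(dosages, dtype=float).ravel():
                if not np.isfinite(d) or d < 0:
                    row.append(None)
                else:
                    row.append(harden_dosage(float(min(d, 2.0)), dosage_tolerance))
            counts[rsid] = row
        else:
            gt = variant.gt_types  # gts012: 0/1/2 = alt count, 3 = unknown
            counts[rsid] = [int(g) if g != 3 else None for g in gt]
    vcf.close()

    missing_sites = sorted(set(TIER1_VARIANTS) - set(counts))
    if missing_sites:
        raise ValueError(
            f"VCF {vcf_path} lacks required CYP2C19 site(s): {', '.join(missing_sites)}"
        )
    return samples, counts


def call_cohort(
    vcf_path: str,
    dosage_tolerance: float = 0.1,
    prefer_dosage: bool = False,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> CohortCalls:
    """Call CYP2C19 diplotype and metaboliser status for every VCF sample.

    Sites are matched by the VCF ID column against the tier-1 rsIDs, with
    an optional fallback ``positions`` map rsID -> (chrom, 1-based pos) so
    no genome build is hard-coded.  When ``prefer_dosage`` is set and the
    record carries a DS FORMAT field, imputed dosages are hardened with
    :func:`harden_dosage`; otherwise GT hard calls are used.

    Samples with a missing genotype at any site, or an indeterminate
    genotype pattern, are reported in ``excluded`` with a reason and
    logged — never silently dropped.
    """
    samples, counts = _read_vcf_counts(
        vcf_path, dosage_tolerance, prefer_dosage, positions
    )

    rows = []
    excluded = []
    for i, sample in enumerate(samples):
        calls = {rsid: counts[rsid][i] for rsid in TIER1_VARIANTS}
        missing = [rsid for rsid, c in calls.items() if c is None]
        if missing:
            excluded.append({"sample_id": sample, "reason": f"missing:{missing[0]}"})
            continue
        diplotype = genotypes_to_diplotype(calls)
        if diplotype == INDETERMINATE:
            excluded.append({"sample_id": sample, "reason": INDETERMINATE})
            continue
        rows.append(
            {
                "sample_id": sample,
                "diplotype": diplotype_name(diplotype),
                "status": diplotype_to_status(diplotype),
            }
        )
    calls_df = pd.DataFrame(rows, columns=["sample_id", "diplotype", "status"])
    excluded_df = pd.DataFrame(excluded, columns=["sample_id", "reason"])
    n_missing = int(excluded_df["reason"].str.startswith("missing").sum())
    n_indet = int((excluded_df["reason"] == INDETERMINATE).sum())
    logger.info(
        "call_cohort: n_called=%d n_missing=%d n_indeterminate=%d",
        len(calls_df),
        n_missing,
        n_indet,
    )
    return CohortCalls(calls=calls_df, excluded=excluded_df)
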