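"""Shared fixtures: tiny hand-built VCFs and small seeded cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pgxresponse.cohort import CohortConfig, generate_cohort

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=10>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def make_vcf(path, samples, rows, fmt="GT", extra_format_header=""):
    """Write a minimal VCF.

    ``rows`` is a list of (chrom, pos, rsid, ref, alt, per-sample values).
    """
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        if extra_format_header:
            fh.write(extra_format_header)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, rsid, ref, alt, values in rows:
            fh.write(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(values)
                + "\n"
            )
    return path


@pytest.fixture
def toy_vcf(tmp_path):
    """Four samples with hand-derived diplotypes:

    S1 no variant alleles -> *1/*1 (normal)
    S2 rs4244285 hom -> *2/*2 (poor)
    S3 rs12248560 + rs4244285 het -> *2/*17 trans (intermediate)
    S4 rs12248560 hom -> *17/*17 (ultrarapid)
    """
    samples = ["S1", "S2", "S3", "S4"]
    rows = [
        ("10", 96521657, "rs12248560", "C", "T", ["0/0", "0/0", "0/1", "1/1"]),
        ("10", 96540410, "rs4986893", "G", "A", ["0/0", "0/0", "0/0", "0/0"]),
        ("10", 96541616, "rs4244285", "G", "A", ["0/0", "1/1", "0/1", "0/0"]),
    ]
    return make_vcf(tmp_path / "toy.vcf", samples, rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-participant cohort with default (null) settings, fixed seed."""
    cfg = CohortConfig(n_participants=600, seed=123)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
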