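"""Shared fixtures: a session-scoped synthetic scenario and callset builders."""

from __future__ import annotations

import pytest

from indelfinger.comparison import classify_fixed
from indelfinger.filtering import run_filter_cascade
from indelfinger.models import CallSet, SampleGenotype, VariantSite
from indelfinger.synthetic import ScenarioConfig, generate


def make_site(contig="c1", pos=100, ref="A", alts=("G",), qual=500.0, ann=None):
    return VariantSite(contig, pos, ref, tuple(alts), qual, dict(ann or {}))


def make_gt(sample, gt, dp=30, gq=90, ad=None):
    """Genotype with sensible AD defaults for the given call."""
    if gt is None:
        return SampleGenotype(sample, None, dp=0, gq=0, ad=None)
    if ad is None:
        if gt[0] == gt[1]:
            ad = [0, 0]
            ad[gt[0]] = dp
        else:
            ad = [dp // 2, dp - dp // 2]
    return SampleGenotype(sample, tuple(gt), dp=dp, gq=gq, ad=tuple(ad))


def make_callset(samples, rows):
    """Rows of (site, {sample: gt_tuple_or_None}) with auto AD/DP/GQ."""
    sites, genotypes = [], []
    for site, gts in rows:
        sites.append(site)
        genotypes.append({s: make_gt(s, gts[s]) for s in samples})
    cs = CallSet(tuple(samples), sites, genotypes)
    cs.sort()
    return cs


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario (seed 1), shared across the suite."""
    return generate(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def filtered(scenario):
    callset, report = run_filter_cascade(scenario.callset)
    return callset, report


@pytest.fixture(scope="session")
def classified(scenario, filtered):
    callset, _ = filtered
    a, b = scenario.truth["focal_pair"]
    return callset, classify_fixed(callset, a, b)
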