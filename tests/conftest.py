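"""Shared fixtures.  Expensive pipeline runs are session-scoped so the
unit tests and the acceptance checks reuse the same computations."""

from __future__ import annotations

import numpy as np
import pytest

from rbpdetect.classifier import embed, nested_cv
from rbpdetect.curation import CurationConfig, curate_dataset
from rbpdetect.domains import construct_custom_hmms, is_rbp_by_domains, scan_proteins
from rbpdetect.profile_hmm import Msa, build_from_msa
from rbpdetect.synthetic import (
    GenBankFixtureSpec,
    ModularFixtureSpec,
    TwoClassSpec,
    gen_decoys,
    gen_genbank,
    gen_modular_proteins,
    gen_two_class,
)

#: reduced grid used by the test-suite CV runs; the tuned names match the
#: production grid, the values keep single-CPU runs short
CV_GRID = {"max_depth": [3, 5], "n_estimators": [100, 300]}


@pytest.fixture(scope="session")
def toy_hmm():
    return build_from_msa(Msa(["ACDE"] * 5), name="toy")


@pytest.fixture(scope="session")
def genbank_fixture(tmp_path_factory):
    """1,000-CDS annotated-genome fixture with ground truth."""
    out = tmp_path_factory.mktemp("genbank")
    spec = GenBankFixtureSpec(seed=11)
    paths, truth = gen_genbank(spec, out)
    return spec, paths, truth


@pytest.fixture(scope="session")
def curated(genbank_fixture):
    _, paths, _ = genbank_fixture
    return curate_dataset(paths, CurationConfig(subsample_ratio=None))


@pytest.fixture(scope="session")
def modular_fixture():
    return gen_modular_proteins(ModularFixtureSpec(seed=5))


@pytest.fixture(scope="session")
def custom_hmm_run(modular_fixture):
    """The full custom-HMM construction pipeline on the modular fixture."""
    fix = modular_fixture
    augmented, report = construct_custom_hmms(fix.sequences, fix.base_hmms)
    return fix, augmented, report


@pytest.fixture(scope="session")
def holdout_scan(custom_hmm_run):
    fix, augmented, _ = custom_hmm_run
    archs = scan_proteins(fix.holdout, augmented)
    decoys = gen_decoys(fix.holdout, seed=77, n=100)
    decoy_archs = scan_proteins(decoys, augmented)
    return archs, decoy_archs


@pytest.fixture(scope="session")
def separable_cv():
    """Nested CV on the separable two-class fixture (n=500)."""
    data = gen_two_class(TwoClassSpec(seed=21))
    X = embed(data.sequences, data.ids)
    report, bundle = nested_cv(X, data.labels, grid=CV_GRID, seed=21)
    return data, X, report, bundle


@pytest.fixture(scope="session")
def null_cv_runs():
    """Nested CV with effect size 0 over ten seeds (reduced problem size)."""
    aps, prevs = [], []
    for seed in range(10):
        data = gen_two_class(TwoClassSpec(seed=seed, n=220, effect_size=0.0))
        X = embed(data.sequences, data.ids)
        report, _ = nested_cv(
            X, data.labels, grid={"max_depth": [3], "n_estimators": [50]}, seed=seed
        )
        aps.append(report.mean_pr_auc)
        prevs.append(data.labels.mean())
    return np.array(aps), float(np.mean(prevs))


@pytest.fixture(scope="session")
def fusion_cv_runs():
    """Embeddings-only vs fused CV on a fixture where only HMM scores carry
    signal (sequences are pure background)."""
    from rbpdetect.classifier import fuse_features

    data = gen_two_class(TwoClassSpec(seed=31, n=300, effect_size=0.0, hmm_effect=40.0))
    X = embed(data.sequences, data.ids)
    grid = {"max_depth": [3], "n_estimators": [100]}
    rep_embed, _ = nested_cv(X, data.labels, grid=grid, seed=31)
    Xf = fuse_features(X, data.hmm_scores, data.hmm_names)
    rep_fused, _ = nested_cv(Xf, data.labels, grid=grid, seed=31)
    return rep_embed, rep_fused
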