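"""Shared fixtures: all data is generated in-process, nothing is downloaded.

The expensive pieces — the standard synthetic world, its preprocessed and
image-converted form, and the trained classifiers — are session-scoped and
shared between the module tests and the acceptance suite, so the CNN is
trained once per configuration for the whole run.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from scpix.annotate import annotate, calibrate_unknown_threshold, evaluate_annotation
from scpix.classifier import TrainConfig, predict_proba, split_train_val, train
from scpix.containers import ExpressionMatrix
from scpix.mapping import ImageStack, build_feature_map, cells_to_images, embed_features
from scpix.pipeline import PipelineConfig, preprocess_pair
from scpix.simulate import SimSpec, simulate_counts, standard_fixture

EMBED_SEED = 7
TRAIN_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def standard_world():
    """The canonical 5-type reference/query pair with planted truth."""
    return standard_fixture()


@pytest.fixture(scope="session")
def standard_pipeline(standard_world):
    """Standard world preprocessed and converted to images (both query arms).

    ``query_images[True]`` is the batch-corrected query arm,
    ``query_images[False]`` the uncorrected ablation arm; the reference and
    the feature map are shared.
    """
    ref, query, truth = standard_world
    ref_scaled, q_corrected, scaling, reports = preprocess_pair(
        ref, query, PipelineConfig()
    )
    _, q_raw, _, _ = preprocess_pair(
        ref, query, PipelineConfig(batch_correction=False)
    )
    coords = embed_features(ref_scaled, "tsne", perplexity=30.0, seed=EMBED_SEED)
    fmap = build_feature_map(
        coords, ref_scaled.gene_ids, pixel_size=64,
        perplexity=30.0, seed=EMBED_SEED, method="tsne",
    )
    return SimpleNamespace(
        truth=truth,
        scaling=scaling,
        reports=reports,
        ref_scaled=ref_scaled,
        query_scaled={True: q_corrected, False: q_raw},
        fmap=fmap,
        ref_images=cells_to_images(ref_scaled, fmap),
        query_images={
            True: cells_to_images(q_corrected, fmap),
            False: cells_to_images(q_raw, fmap),
        },
    )


def _train_and_annotate(sp, seed: int, batch_correction: bool):
    """One full supervised run: train, calibrate the 1% unknown threshold on
    reference validation cells, annotate the query, score against truth."""
    cfg = TrainConfig(max_epochs=30, seed=seed)
    model = train(sp.ref_images, sp.ref_scaled.cell_type, cfg)
    _, val_idx = split_train_val(
        sp.ref_images, sp.ref_scaled.cell_type, cfg.val_fraction, cfg.seed
    )
    val = ImageStack(
        sp.ref_images.pixels[val_idx],
        sp.ref_images.cell_ids[val_idx],
        sp.ref_images.map_ref,
    )
    val_proba = predict_proba(model, val)
    threshold = calibrate_unknown_threshold(val_proba, quantile=0.01)
    query_scaled = sp.query_scaled[batch_correction]
    proba = predict_proba(model, sp.query_images[batch_correction])
    pred = annotate(proba, model.class_names, threshold, query_scaled.cell_ids)
    metrics = evaluate_annotation(pred, query_scaled.cell_type, novel_label="novel")
    return SimpleNamespace(
        model=model, threshold=threshold, pred=pred, metrics=metrics,
        val_proba=val_proba,
    )


@pytest.fixture(scope="session")
def acceptance_runs(standard_pipeline):
    """Three seed-paired runs per batch-correction arm (six trainings)."""
    return {
        bc: {s: _train_and_annotate(standard_pipeline, s, bc) for s in TRAIN_SEEDS}
        for bc in (True, False)
    }


@pytest.fixture(scope="session")
def trained_run(acceptance_runs):
    """The canonical seed-1, batch-corrected run."""
    return acceptance_runs[True][TRAIN_SEEDS[0]]


@pytest.fixture(scope="session")
def small_world():
    """A fast 3-type world (120 genes) for plumbing tests.

    Gene panels this small violate the default QC feature floor, so tests
    using it either skip QC or pass scaled-down thresholds.
    """
    spec = SimSpec(
        n_types=3,
        cells_per_type=60,
        query_cells_per_type=30,
        n_genes=120,
        n_markers_per_type=4,
        novel_cells=20,
        mt_genes=5,
        frac_qc_violators=0.0,
        seed=7,
    )
    return simulate_counts(spec)


@pytest.fixture()
def tiny_counts():
    """A hand-written 3-cell x 4-gene counts matrix with one MT- gene."""
    return ExpressionMatrix(
        values=np.array(
            [
                [2.0, 1.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
                [5.0, 0.0, 3.0, 2.0],
            ]
        ),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        gene_ids=np.array(["GA", "MT-1", "MT-2", "GB"], dtype=object),
        layer_tag="counts",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
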