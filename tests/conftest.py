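"""Shared fixtures: a desk-scale trained classifier setup reused by the
classifier, pipeline, and acceptance tests (training a GIST/SVM stack is the
expensive step, so it is built once per session)."""
from __future__ import annotations

import numpy as np
import pytest

from scenefield import degrade as dg
from scenefield import synthetic as syn
from scenefield.classify import train_classifier
from scenefield.gist import build_filter_bank, gist_matrix

SETUP_SIZE_PX = 128


@pytest.fixture(scope="session")
def bank128():
    return build_filter_bank(SETUP_SIZE_PX)


@pytest.fixture(scope="session")
def trained_setup(bank128):
    """Clean-trained classifier plus an equalized evaluation pool.

    Categories are the default cardinal- vs oblique-dominant spectral
    families; training uses 50 clean images per class and the pool holds 100
    per class for degraded evaluation.
    """
    n = SETUP_SIZE_PX
    params_a = syn.SceneParams.cardinal(n)
    params_b = syn.SceneParams.oblique(n)
    train_imgs = dg.equalize_set(
        syn.generate_scene_set(params_a, params_b, 50, seed=101)
    )
    pool_imgs = dg.equalize_set(
        syn.generate_scene_set(params_a, params_b, 100, seed=202)
    )
    X_train = gist_matrix(train_imgs, bank128)
    y_train = np.array([im.label for im in train_imgs])
    model = train_classifier(X_train, y_train, task="naturalness")
    return {
        "size_px": n,
        "bank": bank128,
        "model": model,
        "train_images": train_imgs,
        "train_features": X_train,
        "train_labels": y_train,
        "pool_images": pool_imgs,
        "pool_labels": np.array([im.label for im in pool_imgs]),
        "set_mean": float(np.mean([im.pixels.mean() for im in pool_imgs])),
    }


def evaluate_condition(setup, snr_db, vfd_kind, indices, rng):
    """Degrade the indexed pool stimuli for one condition and return
    (features, labels)."""
    spec = dg.DegradationSpec(
        snr_db=snr_db,
        vfd=syn.generate_vfd(vfd_kind, setup["size_px"]),
        fill_value=setup["set_mean"],
    )
    degraded = [
        dg.degrade(setup["pool_images"][i], spec, set_mean=setup["set_mean"], rng=rng)
        for i in indices
    ]
    X = gist_matrix(degraded, setup["bank"])
    y = setup["pool_labels"][list(indices)]
    return X, y
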