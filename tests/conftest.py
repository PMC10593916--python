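import numpy as np
import pytest

import neurostim as ns
from neurostim import synthetic_data as sd


@pytest.fixture(scope="session")
def bank64():
    return ns.default_bank(0, image_side=64)


@pytest.fixture(scope="session")
def bank32():
    return ns.default_bank(0, image_side=32)


@pytest.fixture(scope="session")
def bank16():
    return ns.default_bank(0, image_side=16)


@pytest.fixture(scope="session")
def small_pool():
    """24 natural images at 32 px, 4 classes."""
    return sd.make_pool(2, 10, 4, 4, seed=11, side=32)


def gt_encoding_model(bank, tuning, center, radius, *, bias=0.0, region="R",
                      subject_id="gt"):
    """Encoding model whose readout equals a ground-truth fwRF subject."""
    return ns.EncodingModel(
        bank_id=bank.bank_id,
        selected_channels=np.arange(bank.n_channels_total),
        field=ns.PoolingField(center=center, radius=radius),
        weights=np.asarray(tuning, dtype=float), bias=bias, region=region,
        subject_id=subject_id, bank=bank)


@pytest.fixture(scope="session")
def gt_model(bank32):
    rng = np.random.default_rng(5)
    return gt_encoding_model(bank32, rng.standard_normal(32), (0.7, -0.7),
                             0.15)


@pytest.fixture(scope="session")
def tiny_config(tmp_path_factory):
    """A reduced-size pipeline configuration that preserves the experiment's
    structure (two sessions, all stages) at a few-minute desk scale."""
    out = tmp_path_factory.mktemp("pipeline") / "tiny"
    return ns.PipelineConfig(
        seed=7, outdir=str(out),
        n_base_subjects=3, n_novel_subjects=3,
        n_unique_per_subject=30, n_shared=12, n_classes=6,
        regions=("FFA1", "EBA"),
        set_size=6, session2_counts=(4, 3, 2), n_train_per_cell=3,
        n_gen_classes=5, n_probe_per_class=20, n_top_classes=2,
        synth_steps=20, n_perm=200,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    manifest = ns.full_run(tiny_config)
    return tiny_config, manifest
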