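import numpy as np
import pytest

from graylift import (
    GrayImage,
    InvalidInputError,
    SyntheticSpec,
    TrainingConfig,
    ablation_run,
    generate,
    residual_report,
    unit_weight_schedule,
)
from graylift.synthetic import KINDS

from .conftest import SMOKE_TRAINING


class TestGenerator:
    def test_constant_kind(self):
        img = generate(SyntheticSpec("constant", 9, 5, seed=1, value=77))
        assert img.values.shape == (5, 9)
        assert np.all(img.values == 77)

    @pytest.mark.parametrize("kind", KINDS)
    def test_deterministic_under_seed(self, kind):
        a = generate(SyntheticSpec(kind, 24, 16, seed=9))
        b = generate(SyntheticSpec(kind, 24, 16, seed=9))
        assert a == b

    def test_seed_changes_noise_field(self):
        a = generate(SyntheticSpec("uniform-noise", 24, 16, seed=9))
        c = generate(SyntheticSpec("uniform-noise", 24, 16, seed=10))
        assert not np.array_equal(a.values, c.values)

    def test_gradient_rows_strictly_monotone(self):
        for seed in range(5):
            img = generate(SyntheticSpec("gradient", 30, 40, seed=seed))
            means = img.values.mean(axis=1)
            d = np.diff(means)
            assert np.all(d > 0) or np.all(d < 0)

    def test_phantom_has_edges_and_smooth_regions(self):
        img = generate(SyntheticSpec("ct-phantom", 64, 64, seed=3)).values
        assert img.max() > 200 and img.min() < 20  # rim vs air
        grad = np.abs(np.diff(img.astype(int), axis=0))
        assert grad.max() > 80       # sharp edge somewhere
        assert np.median(grad) <= 5  # mostly smooth

    def test_invalid_kind_rejected(self):
        with pytest.raises(InvalidInputError):
            SyntheticSpec("perlin", 8, 8)


class TestResidualReport:
    def test_histogram_conservation_and_accounting(self, untrained_bundle):
        img = generate(SyntheticSpec("gaussian-blobs", 30, 22, seed=4))
        rep = residual_report(img, untrained_bundle)
        gh, gw = (22 + 1) // 2, (30 + 1) // 2
        assert rep.histogram.sum() == 3 * gh * gw
        parts = rep.base_bpp + rep.header_bpp + sum(rep.subimage_bpp.values())
        assert parts == pytest.approx(rep.total_bpp, abs=1e-12)
        assert rep.total_bpp >= max(rep.subimage_bpp.values())

    def test_trained_mode_at_center(self, smoke_bundle):
        img = generate(SyntheticSpec("gradient", 32, 32, seed=999))
        assert residual_report(img, smoke_bundle).mode_class == 255


@pytest.fixture(scope="module")
def tiny_cfgs():
    base = dict(SMOKE_TRAINING)
    base.update(epochs=2, patches_per_epoch=8)
    cfg_plain = TrainingConfig(**base, weight_schedule=unit_weight_schedule())
    cfg_weighted = TrainingConfig(**base)
    return cfg_plain, cfg_weighted


class TestAblation:
    def test_table_layout_and_nonnegativity(self, tiny_cfgs, smooth_pool):
        cfg_plain, cfg_weighted = tiny_cfgs
        eval_imgs = [GrayImage(v) for v in smooth_pool[:2]]
        table = ablation_run(smooth_pool[:6], cfg_plain, cfg_weighted, eval_imgs)
        assert table.rows == ("B", "C", "D", "Total")
        for col in (table.model1, table.model2):
            assert set(col) == {"B", "C", "D", "Total"}
            assert all(v >= 0 for v in col.values())
            assert col["Total"] == pytest.approx(col["B"] + col["C"] + col["D"])
        text = table.to_text()
        assert "Total" in text and "Model1" in text
        assert table.to_csv().count("\n") == 4

    def test_identical_configs_identical_table(self, tiny_cfgs, smooth_pool):
        cfg_plain, _ = tiny_cfgs
        eval_imgs = [GrayImage(smooth_pool[0])]
        t = ablation_run(smooth_pool[:4], cfg_plain, cfg_plain, eval_imgs)
        assert t.model1 == t.model2

    def test_configs_must_differ_only_in_schedule(self, tiny_cfgs, smooth_pool):
        cfg_plain, _ = tiny_cfgs
        other = TrainingConfig(
            **{**SMOKE_TRAINING, "epochs": 3, "patches_per_epoch": 8}
        )
        with pytest.raises(InvalidInputError):
            ablation_run(smooth_pool[:2], cfg_plain, other)
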