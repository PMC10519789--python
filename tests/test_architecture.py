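"""Model construction, parameter accounting and the layer search space.

Parameter oracles: the 1000-class baseline differs from the 6-class one by
exactly the classifier head (1280 * delta_classes + delta_classes), and
per-block costs must be additive — removing one deep-stage repeat always
removes the same number of scalars regardless of the other stages."""

import numpy as np
import pytest

import fcaeffnet.autograd as ag
from fcaeffnet.architecture import (ArchitectureSpec, baseline_b0, block_configs,
                                    build_model, count_macs, count_params,
                                    enumerate_search_space, final_spec,
                                    stage_specs, summarize)
from fcaeffnet.autograd import Tensor, softmax
from fcaeffnet.layers import Conv2d


class TestParameterCounting:
    def test_single_conv_counts_weights_only(self):
        assert Conv2d(3, 6, 1, bias=False).num_params() == 18

    def test_baseline_exact_count(self):
        model = build_model(baseline_b0(num_classes=6))
        assert count_params(model) == 4_015_234

    def test_classifier_head_arithmetic(self):
        p6 = count_params(build_model(baseline_b0(num_classes=6)))
        p1000 = count_params(build_model(baseline_b0(num_classes=1000)))
        assert p1000 - p6 == (1280 * 1000 + 1000) - (1280 * 6 + 6)
        assert p1000 == pytest.approx(5.29e6, abs=0.005e6)

    def test_block_cost_additivity_across_search_space(self):
        base = final_spec()
        counts = {spec.layers_567: count_params(build_model(spec))
                  for spec in enumerate_search_space(base)}
        # removing a stage-7 repeat always costs the same number of scalars
        deltas7 = {counts[(s5, s6, s7 + 1)] - counts[(s5, s6, s7)]
                   for s5 in (2, 3) for s6 in (2, 3) for s7 in (2, 3)}
        assert len(deltas7) == 1
        deltas6 = {counts[(s5, 3, s7)] - counts[(s5, 2, s7)]
                   for s5 in (2, 3) for s7 in (2, 3, 4)}
        assert len(deltas6) == 1
        deltas5 = {counts[(3, s6, s7)] - counts[(2, s6, s7)]
                   for s6 in (2, 3) for s7 in (2, 3, 4)}
        assert len(deltas5) == 1

    def test_fusion_node_changes_count_negligibly(self):
        for node in ("node1", "node2", "node3"):
            with_af = ArchitectureSpec(attention="se", norm="bn",
                                       activation="swish", af_node=node,
                                       layers_567=(3, 3, 4))
            without = ArchitectureSpec(attention="se", norm="bn",
                                       activation="swish", af_node="none",
                                       layers_567=(3, 3, 4))
            delta = (count_params(build_model(with_af))
                     - count_params(build_model(without)))
            assert 0 < delta < 5_000


class TestMacCounting:
    def test_pointwise_conv_on_unit_input(self):
        spec = baseline_b0()
        model = build_model(spec)
        # 1x1 conv, 1 -> 1 channel, on a 1x1 input contributes exactly 1 MAC
        assert Conv2d(1, 1, 1, bias=False).macs(1, 1)[0] == 1
        assert count_macs(model) > 0

    def test_toy_stack_matches_hand_count(self):
        # two layers on an 8x8 input: 3x3 conv 3->4 same (stride 1), then
        # 1x1 conv 4->2: 9*3*4*64 + 4*2*64 = 6912 + 512
        c1 = Conv2d(3, 4, 3, padding="same", bias=False)
        c2 = Conv2d(4, 2, 1, bias=False)
        m1, h, w = c1.macs(8, 8)
        m2, _, _ = c2.macs(h, w)
        assert m1 + m2 == 9 * 3 * 4 * 64 + 4 * 2 * 64

    def test_trimming_reduces_macs(self):
        big = count_macs(build_model(ArchitectureSpec(layers_567=(3, 3, 4))))
        small = count_macs(build_model(ArchitectureSpec(layers_567=(2, 2, 2))))
        assert small < big


class TestSearchSpace:
    def test_enumerates_twelve_variants_in_printed_order(self):
        specs = enumerate_search_space()
        assert len(specs) == 12
        triples = [s.layers_567 for s in specs]
        assert triples[0] == (2, 2, 2)
        assert triples[3] == (2, 3, 2)
        assert triples[-1] == (3, 3, 4)
        assert all(t <= (3, 3, 4) for t in triples)
        assert triples == sorted(triples)

    def test_invalid_triples_rejected(self):
        with pytest.raises(ValueError, match="layers_567"):
            ArchitectureSpec(layers_567=(0, 3, 2))
        with pytest.raises(ValueError, match="layers_567"):
            ArchitectureSpec(layers_567=(2, 4, 2))
        with pytest.raises(ValueError, match="af_node"):
            ArchitectureSpec(af_node="node9")


class TestBuiltModel:
    def test_forward_yields_normalised_class_scores(self, tiny_model):
        tiny_model.eval()
        x = np.random.default_rng(0).normal(0, 1, (2, 3, 32, 32)).astype(np.float32)
        with ag.no_grad():
            logits = tiny_model.forward(Tensor(x)).numpy()
        assert logits.shape == (2, 6)
        np.testing.assert_allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-5)

    def test_full_resolution_forward_shape(self):
        model = build_model(final_spec(), seed=0)
        model.eval()
        x = np.zeros((1, 3, 224, 224), np.float32)
        with ag.no_grad():
            logits = model.forward(Tensor(x)).numpy()
        assert logits.shape == (1, 6)

    def test_rebuild_is_deterministic(self, tiny_arch):
        a = build_model(tiny_arch, seed=11)
        b = build_model(tiny_arch, seed=11)
        assert count_params(a) == count_params(b)
        x = np.random.default_rng(1).normal(0, 1, (1, 3, 32, 32)).astype(np.float32)
        a.eval(), b.eval()
        with ag.no_grad():
            assert np.array_equal(a.forward(Tensor(x)).numpy(),
                                  b.forward(Tensor(x)).numpy())

    def test_fusion_weight_zero_recovers_fusion_free_network(self, rng):
        spec_af = ArchitectureSpec(layers_567=(1, 1, 1), input_resolution=32,
                                   af_node="node2")
        spec_no = ArchitectureSpec(layers_567=(1, 1, 1), input_resolution=32,
                                   af_node="none")
        with_af = build_model(spec_af, seed=5)
        without = build_model(spec_no, seed=6)
        shared = {k: v for k, v in with_af.state_dict().items()
                  if not k.startswith("af.")}
        without.load_state_dict(shared)
        with_af.af.w1.data[:] = 0.0
        with_af.af.w2.data[:] = 1.0
        x = rng.normal(0, 1, (2, 3, 32, 32)).astype(np.float32)
        with_af.eval(), without.eval()
        with ag.no_grad():
            ya = with_af.forward(Tensor(x)).numpy()
            yb = without.forward(Tensor(x)).numpy()
        np.testing.assert_allclose(ya, yb, atol=1e-6)


class TestStagePlanMetadata:
    def test_resolution_halves_exactly_at_stride_two(self):
        rows = stage_specs(final_spec())
        res = [r.in_resolution for r in rows]
        assert res[0] == 224 and res[1] == 112
        for prev, row in zip(rows[1:], rows[2:]):
            if row.operator == "mbconv":
                expected = prev.in_resolution // prev.stride if prev.stride == 2 \
                    else prev.in_resolution
                assert row.in_resolution == expected

    def test_branch_drop_ramp_matches_stage_factors(self):
        cfgs = block_configs(final_spec())
        stage_first = {}
        for cfg in cfgs:
            stage_first.setdefault(cfg.out_channels, cfg.drop_rate)
        assert stage_first[16] == pytest.approx(0.0125)
        assert stage_first[24] == pytest.approx(0.025)
        assert stage_first[40] == pytest.approx(0.05)
        assert stage_first[80] == pytest.approx(0.075)
        assert stage_first[112] == pytest.approx(0.1)
        assert stage_first[192] == pytest.approx(0.1375)
        assert stage_first[320] == pytest.approx(0.1625)

    def test_summary_lists_every_stage(self):
        text = summarize(ArchitectureSpec(layers_567=(2, 3, 2),
                                          input_resolution=224))
        assert "FCA-MBConv6" in text and "Conv1x1 & Pooling & FC" in text
        assert text.count("MBConv") == 7
        assert "total:" in text

    def test_config_yaml_round_trip(self, tmp_path):
        spec = ArchitectureSpec(attention="ca", norm="bn", activation="swish",
                                af_node="node1", layers_567=(3, 2, 4),
                                num_classes=9, input_resolution=96)
        path = tmp_path / "arch.yaml"
        spec.to_yaml(path)
        assert ArchitectureSpec.from_yaml(path) == spec
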