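"""Architecture contracts: RSU blocks, GCM skips, RAG gate, assembly."""

import numpy as np
import pytest

import organoidseg as og
from organoidseg import nn
from organoidseg.model import GCM, RAG, RAGConfig, RSUConfig, ConfigError
from organoidseg.nn import Tensor

rng = np.random.default_rng(0)


class TestRSU:
    def test_level7_preserves_spatial_size(self):
        blk = og.build_rsu(RSUConfig(7, 3, 4, 8), rng=rng)
        out = blk(Tensor(rng.normal(size=(1, 3, 96, 96)).astype(np.float32)))
        assert out.data.shape == (1, 8, 96, 96)

    def test_dilated_keeps_all_internal_resolutions(self):
        blk = og.build_rsu(RSUConfig(4, 16, 8, 16, dilated=True), rng=rng)
        out = blk(Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32)))
        assert out.data.shape == (1, 16, 8, 8)
        assert all(s[2:] == (8, 8) for s in blk.last_internal_shapes)

    def test_zero_input_gives_finite_output(self):
        blk = og.build_rsu(RSUConfig(5, 2, 4, 4), rng=rng)
        out = blk(Tensor(np.zeros((1, 2, 32, 32), np.float32)))
        assert np.isfinite(out.data).all()

    def test_too_deep_for_resolution_rejected(self):
        blk = og.build_rsu(RSUConfig(7, 2, 4, 4), rng=rng)
        with pytest.raises(ValueError, match="pools below"):
            blk(Tensor(np.zeros((1, 2, 16, 16), np.float32)))


class TestGCM:
    @pytest.mark.parametrize("n,c", [(4, 64), (6, 48), (8, 64), (6, 256)])
    def test_channel_halving_law(self, n, c):
        gcm = GCM(c, c, n, rng=rng)
        s = Tensor(rng.normal(size=(1, c, 8, 8)).astype(np.float32))
        d = Tensor(rng.normal(size=(1, c, 8, 8)).astype(np.float32))
        out = gcm(s, d)
        assert out.data.shape == (1, (c + c) // 2, 8, 8)

    def test_unequal_channel_counts_halve_to_mean(self):
        gcm = GCM(32, 64, 4, rng=rng)
        s = Tensor(rng.normal(size=(1, 32, 4, 4)).astype(np.float32))
        d = Tensor(rng.normal(size=(1, 64, 4, 4)).astype(np.float32))
        assert gcm(s, d).data.shape == (1, 48, 4, 4)

    def test_zeroed_convs_isolate_residual_path(self):
        gcm = GCM(16, 16, 4, rng=rng)
        for conv in gcm.group_convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        s = Tensor(rng.normal(size=(1, 16, 6, 6)).astype(np.float32))
        d = Tensor(rng.normal(size=(1, 16, 6, 6)).astype(np.float32))
        assert np.allclose(gcm(s, d).data, d.data)

    def test_carry_is_resized_projected_and_summed(self):
        gcm = GCM(16, 16, 4, carry_channels=8, rng=rng)
        for conv in gcm.group_convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        s = Tensor(np.zeros((1, 16, 6, 6), np.float32))
        d = Tensor(rng.normal(size=(1, 16, 6, 6)).astype(np.float32))
        carry = Tensor(rng.normal(size=(1, 8, 3, 3)).astype(np.float32))
        out = gcm(s, d, carry)
        # residual path returns deep + projected carry
        proj = gcm.carry_proj(nn.resize_bilinear(carry, 6, 6))
        assert np.allclose(out.data, d.data + proj.data, atol=1e-5)

    def test_impossible_group_count_rejected_at_build(self):
        with pytest.raises(ConfigError):
            GCM(4, 4, 8, rng=rng)
        with pytest.raises(ConfigError):
            GCM(3, 4, 2, rng=rng)  # odd total cannot be halved


class TestRAG:
    def test_attention_weights_strictly_in_unit_interval(self):
        rag = RAG(16, 32, rng=rng)
        x = Tensor(rng.normal(size=(2, 16, 16, 16)).astype(np.float32))
        g = Tensor(rng.normal(size=(2, 32, 8, 8)).astype(np.float32))
        rag(x, g)
        assert (rag.last_attention > 0).all() and (rag.last_attention < 1).all()

    def test_forced_half_attention_gives_1p5_times_filtered_map(self):
        rag = RAG(16, 16, rng=rng)
        rag.fc2.weight.data[:] = 0
        rag.fc2.bias.data[:] = 0  # sigmoid(0) = 0.5 for every channel
        x = Tensor(rng.normal(size=(1, 16, 12, 12)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 16, 6, 6)).astype(np.float32))
        out = rag(x, g)
        dphi = rag.d(nn.relu(rag.a(x) + rag.b(nn.resize_bilinear(g, 12, 12))))
        assert np.allclose(out.data, 1.5 * dphi.data, atol=1e-5)

    def test_output_shape_follows_x(self):
        rag = RAG(64, 128, RAGConfig(), rng=rng)
        x = Tensor(rng.normal(size=(1, 64, 32, 32)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 128, 16, 16)).astype(np.float32))
        assert rag(x, g).data.shape == (1, 64, 32, 32)

    def test_wrong_gating_resolution_rejected(self):
        rag = RAG(8, 8, rng=rng)
        x = Tensor(np.zeros((1, 8, 16, 16), np.float32))
        g = Tensor(np.zeros((1, 8, 16, 16), np.float32))
        with pytest.raises(ValueError, match="half resolution"):
            rag(x, g)


class TestAssembledNetwork:
    def test_forward_emits_seven_unit_interval_maps(self, tiny_model):
        x = Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
        tiny_model.eval()
        with nn.no_grad():
            out = tiny_model(x)
        maps = [out["fused"]] + out["sides"]
        assert len(maps) == 7
        for m in maps:
            assert m.data.shape == (1, 1, 64, 64)
            # valid probabilities (sigmoid may saturate at float32 precision)
            assert (m.data >= 0).all() and (m.data <= 1).all()

    def test_bottleneck_is_one_thirtysecond_of_input(self, tiny_model):
        stages = og.forward_backbone(tiny_model, rng.random((3, 64, 64)).astype(np.float32))
        assert len(stages) == 11
        assert stages["Encoder6"].shape[1:] == (2, 2)

    def test_construction_is_deterministic(self, tiny_cfg):
        m1 = og.assemble_acu2net(tiny_cfg, seed=5)
        m2 = og.assemble_acu2net(tiny_cfg, seed=5)
        assert m1.num_parameters() == m2.num_parameters()
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert s1.keys() == s2.keys()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    @pytest.mark.parametrize(
        "use_rag,use_gcm",
        [(False, False), (True, False), (False, True), (True, True)],
        ids=["plain", "rag", "gcm", "both"],
    )
    def test_ablation_lattice_all_buildable(self, use_rag, use_gcm):
        cfg = og.default_network_config(width_divisor=16, input_hw=(64, 64),
                                        use_rag=use_rag, use_gcm=use_gcm)
        model = og.assemble_acu2net(cfg, seed=1)
        model.eval()
        with nn.no_grad():
            out = model(Tensor(rng.random((1, 3, 64, 64)).astype(np.float32)))
        assert out["fused"].data.shape == (1, 1, 64, 64)
        assert len(out["sides"]) == 6

    def test_indivisible_input_size_reports_requirement(self, tiny_model):
        with pytest.raises(ValueError, match="divisible by 32"):
            tiny_model(Tensor(np.zeros((1, 3, 60, 60), np.float32)))

    def test_config_roundtrip_through_dict(self, tiny_cfg):
        back = og.NetworkConfig.from_dict(tiny_cfg.to_dict())
        assert back == tiny_cfg

    def test_one_gradient_step_decreases_loss(self, overfit_tiles):
        from organoidseg.objectives import combined_loss_t

        cfg = og.default_network_config(width_divisor=16, input_hw=(96, 96), dropout_p=0.0)
        model = og.assemble_acu2net(cfg, seed=2)
        model.train()
        tile = overfit_tiles[0]
        x = Tensor(tile.image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        y = tile.mask.astype(np.float32)[None, None]

        def loss_value():
            out = model(x)
            loss, _ = combined_loss_t(out["fused"], out["sides"], y)
            return loss

        l0 = loss_value()
        opt = nn.SGD(model.parameters(), lr=1e-3)
        opt.zero_grad()
        l0.backward()
        opt.step()
        assert float(loss_value().data) < float(l0.data)


def test_stage_table_matches_forward_shapes(tiny_cfg, tiny_model):
    rows = {r["name"]: r for r in og.stage_table(tiny_cfg, (64, 64))}
    stages = og.forward_backbone(tiny_model, rng.random((3, 64, 64)).astype(np.float32))
    for name, feat in stages.items():
        assert rows[name]["out"] == feat.shape
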