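"""Network construction: rates, propensities, stoichiometry audit."""

import numpy as np
import pytest

from fflcap import (
    TABLE1,
    AffinityVariant,
    build_gene_network,
    build_linear_chain_network,
    build_mapk_network,
    build_minimal_network,
    compose,
    standard_inputs,
)

I2 = standard_inputs(100.0)["I2"]


class TestRateTable:
    def test_printed_values_verbatim(self):
        assert TABLE1["mapk"] == {
            "k1": 15.0, "k": 1.0, "k2": 50.0, "k3": 14.0, "k4": 0.1,
            "k5": 0.15, "n": 1.1, "k6": 0.13, "k7": 0.5, "k8": 0.08,
            "k9": 0.3, "k10": 0.3, "k11": 0.11, "k12": 0.001, "k13": 0.6,
        }
        assert TABLE1["minimal"] == {"k": 20.0, "g": 0.1}
        assert TABLE1["gene"] == {
            "kappa_pm": 0.1, "n_g": 2.0, "K_rp": 100.0, "gamma_pm": 0.2,
            "kappa_m": 14.0, "gamma_m": 1.0, "kappa_p": 20.0, "gamma_p": 0.1,
        }


def _state(net, **overrides):
    s = {sp: 0.0 for sp in net.species}
    s.update(overrides)
    return s


class TestMapkNetwork:
    def test_species_and_reaction_count(self):
        net = build_mapk_network()
        assert net.species == (
            "ppERK_cyt", "ppERK_nuc", "DUSP", "pRSK_nuc",
            "cFos_pre", "cFos_m", "cFos", "pcFos",
        )
        assert len(net.reactions) == 14
        assert net.input_species == "ppERK_cyt"
        assert np.all(net.initial_vector() == 0)

    def test_import_propensity(self):
        net = build_mapk_network()
        rx = {r.name: r for r in net.reactions}["import"]
        assert rx.propensity.value(_state(net, ppERK_cyt=10)) == pytest.approx(150.0)

    def test_hill_at_zero_and_at_half_saturation(self):
        net = build_mapk_network()
        rx = {r.name: r for r in net.reactions}["cfos_pre_production"]
        assert rx.propensity.value(_state(net)) == 0.0
        # Hill equals 1/2 when the activator product equals k6
        st = _state(net, ppERK_nuc=0.13, pRSK_nuc=1.0)
        assert rx.propensity.value(st) == pytest.approx(0.5)

    def test_mean_field_rhs_matches_rate_equations(self):
        """Stoichiometry audit: reconstructed RHS == the published ODEs."""
        net = build_mapk_network()
        p = TABLE1["mapk"]
        rng = np.random.default_rng(0)
        stoich = net.stoichiometry().astype(float)
        for _ in range(20):
            y = rng.uniform(0.0, 30.0, len(net.species))
            state = dict(zip(net.species, y))
            dy = net.propensities(state) @ stoich
            ERKc, ERKn, DUSP, RSK, pre, m, cFos, pcFos = y
            hill = (ERKn * RSK) ** p["n"] / ((ERKn * RSK) ** p["n"] + p["k6"] ** p["n"])
            expected = {
                "ppERK_cyt": -0.0,  # prescribed input: no network reaction moves it
                "ppERK_nuc": p["k1"] * ERKc - ERKn * (p["k2"] + p["k3"] * DUSP),
                "DUSP": p["k"] * ERKn,
                "pRSK_nuc": p["k4"] * ERKn - p["k5"] * RSK,
                "cFos_pre": hill - p["k7"] * pre,
                "cFos_m": p["k7"] * pre - p["k8"] * m,
                "cFos": p["k9"] * m + p["k13"] * pcFos
                - cFos * (p["k10"] + p["k11"] * ERKc),
                "pcFos": p["k11"] * cFos * ERKc - pcFos * (p["k12"] + p["k13"]),
            }
            for i, sp in enumerate(net.species):
                assert dy[i] == pytest.approx(expected[sp], rel=1e-12, abs=1e-12), sp


class TestMinimalNetworks:
    def test_normalization_constants(self):
        net = build_minimal_network(I2)
        assert net.params["G_N"] == pytest.approx(200.0)
        assert net.params["A_N"] == pytest.approx(28.1)
        assert net.params["A_N"] * net.params["G_N"] == pytest.approx(5620.0)

    def test_mean_field_rhs_matches_rate_equations(self):
        k, g = 20.0, 0.1
        A_N, G_N = I2.amplitude, 200.0
        rng = np.random.default_rng(1)
        for builder, ffl in [(build_minimal_network, True), (build_linear_chain_network, False)]:
            net = builder(I2)
            stoich = net.stoichiometry().astype(float)
            for _ in range(10):
                y = rng.uniform(0.0, 6000.0, 5)
                state = dict(zip(net.species, y))
                dy = dict(zip(net.species, net.propensities(state) @ stoich))
                A, B, C, D, E = y
                assert dy["B"] == pytest.approx(k * A - g * B, rel=1e-12)
                assert dy["C"] == pytest.approx(k * B / G_N - g * C, rel=1e-12)
                if ffl:
                    assert dy["D"] == pytest.approx(k * B * C / (A_N * G_N**2) - g * D, rel=1e-12)
                    assert dy["E"] == pytest.approx(k * C * D / (A_N * G_N**2) - g * E, rel=1e-12)
                else:
                    assert dy["D"] == pytest.approx(k * C / G_N - g * D, rel=1e-12)
                    assert dy["E"] == pytest.approx(k * D / G_N - g * E, rel=1e-12)

    def test_shared_fixed_point_is_an_gn(self):
        ss = I2.amplitude * 200.0
        for builder in (build_minimal_network, build_linear_chain_network):
            net = builder(I2)
            state = _state(net, A=I2.amplitude, B=ss, C=ss, D=ss, E=ss)
            dy = net.propensities(state) @ net.stoichiometry().astype(float)
            assert np.allclose(dy[1:], 0.0, atol=1e-9)

    def test_linear_chain_topology(self):
        net = build_linear_chain_network(I2)
        rx = {r.name: r for r in net.reactions}
        # D production reads only C, and vanishes at C = 0
        assert rx["D_production"].propensity.species == ("C",)
        assert rx["D_production"].propensity.value(_state(net, B=100.0)) == 0.0

    def test_bilinear_propensities_vanish_without_activators(self):
        net = build_minimal_network(I2)
        rx = {r.name: r for r in net.reactions}
        assert rx["E_production"].propensity.value(_state(net, B=50.0)) == 0.0

    def test_requires_positive_amplitude(self):
        from fflcap import InputSpec

        with pytest.raises(ValueError):
            # invalid already at the InputSpec level: k1 <= k2
            build_minimal_network(InputSpec(k1=1.0, k2=1.2, T1=1.0, T2=1.0))


class TestGeneNetwork:
    def test_activation_propensity_at_half_saturation(self):
        gene = build_gene_network("pcFos", AffinityVariant.nominal(), name="g")
        rx = {r.name: r for r in gene.reactions}["g:activation"]
        st = _state(gene, pcFos=100.0)
        st["g:P*"] = 1.0
        assert rx.propensity.value(st) == pytest.approx(0.05)
        assert rx.propensity.value(_state(gene)) == 0.0

    def test_affinity_scales_half_saturation(self):
        for variant, k_half in [
            (AffinityVariant.high(), 10.0),
            (AffinityVariant.nominal(), 100.0),
            (AffinityVariant.low(), 1000.0),
        ]:
            gene = build_gene_network("pcFos", variant, name="g")
            rx = {r.name: r for r in gene.reactions}["g:activation"]
            st = _state(gene, pcFos=k_half)
            st["g:P*"] = 1.0
            assert rx.propensity.value(st) == pytest.approx(0.05)

    def test_single_promoter_copy_initial_state(self):
        gene = build_gene_network("pcFos", name="g")
        assert gene.initial_state == {"g:P*": 1}

    def test_fully_active_protein_level(self):
        # with the promoter pinned on, P settles at kappa_m*kappa_p/(gamma_m*gamma_p)
        p = TABLE1["gene"]
        assert p["kappa_m"] * p["kappa_p"] / (p["gamma_m"] * p["gamma_p"]) == 2800.0


class TestCompose:
    def test_species_count(self):
        net = compose(
            build_mapk_network(),
            build_gene_network("pcFos", name="Prt_w"),
            build_gene_network("ppERK_nuc", name="Prt_wo"),
        )
        assert len(net.species) == 8 + 2 * 4

    def test_six_reporter_layout(self):
        genes = [
            build_gene_network("pcFos", v, name=f"W_{v.tag}")
            for v in (AffinityVariant.high(), AffinityVariant.nominal(), AffinityVariant.low())
        ] + [
            build_gene_network("ppERK_nuc", v, name=f"WO_{v.tag}")
            for v in (AffinityVariant.high(), AffinityVariant.nominal(), AffinityVariant.low())
        ]
        net = compose(build_mapk_network(), *genes)
        assert len(net.species) == 8 + 6 * 4
        assert sum(1 for s in net.species if s.endswith(":P")) == 6

    def test_genes_do_not_feed_back_on_host(self):
        host = build_mapk_network()
        net = compose(host, build_gene_network("pcFos", name="g"))
        host_sp = set(host.species)
        for rx in net.reactions[len(host.reactions):]:
            for sp, d in rx.net_change().items():
                assert not (sp in host_sp and d != 0)

    def test_name_clash_rejected(self):
        with pytest.raises(ValueError):
            compose(
                build_mapk_network(),
                build_gene_network("pcFos", name="g"),
                build_gene_network("ppERK_nuc", name="g"),
            )

    def test_unknown_tf_rejected(self):
        with pytest.raises(ValueError):
            compose(build_minimal_network(I2), build_gene_network("pcFos", name="g"))


def test_model_text_export(tmp_path):
    net = build_mapk_network()
    text = net.describe()
    for rx in net.reactions:
        assert rx.name in text
    assert "k11 = 0.11" in text
    path = tmp_path / "model.txt"
    net.to_text(path)
    assert path.read_text() == text
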