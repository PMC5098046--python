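import numpy as np
import pytest

from specnet import (chem, localize_mod, propagate, step_fdr,
                     theoretical_prm, to_prm)
from specnet.align import AlignmentResult
from specnet.network import NetworkNode, build_network
from specnet.propagate import aggregate_fdr, annotations_table
from specnet.simulate import spectrum_from_peptide


def _abstract_network(masses, edge_list, cfg):
    nodes = {f"n{i}": NetworkNode(f"n{i}", m) for i, m in enumerate(masses)}
    edges = []
    for i, j, p in edge_list:
        e = AlignmentResult(f"n{i}", f"n{j}",
                            masses[j] - masses[i], 0.0, 1.0, 1.0)
        e.p1 = e.p2 = e.pair_p = p
        edges.append(e)
    return build_network(edges, nodes, None, cfg)


def test_step_fdr_closed_form():
    assert step_fdr(0.0003, 0.005, 0) == pytest.approx(0.0003, abs=1e-15)
    assert step_fdr(0.0003, 0.005, 1) == pytest.approx(
        1 - 0.9997 * 0.995, abs=1e-15)
    assert step_fdr(0.0003, 0.005, 1) == pytest.approx(0.0052985, abs=1e-12)
    for n in range(11):
        assert step_fdr(0.0003, 0.0, n) == pytest.approx(0.0003, abs=1e-15)


def test_step_fdr_strictly_increases_with_depth():
    vals = [step_fdr(0.0003, 0.005, n) for n in range(12)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_step_fdr_rejects_invalid_rates():
    for a, r, n in ((1.0, 0.1, 1), (-0.1, 0.1, 1), (0.1, 1.0, 1), (0.1, 0.1, -1)):
        with pytest.raises(ValueError):
            step_fdr(a, r, n)


def test_aggregate_fdr_is_id_weighted_mean_over_steps():
    a, r = 0.0003, 0.005
    id_k = [10, 3, 1]
    expected = (3 * step_fdr(a, r, 1) + 1 * step_fdr(a, r, 2)) / 4
    assert aggregate_fdr(id_k, a, r) == pytest.approx(expected, abs=1e-15)
    assert aggregate_fdr([5], a, r) == 0.0


def test_path_propagation_within_budget(cfg):
    # seed - x - y at a = 0.0003, r = 0.005: aggregate (FDR1+FDR2)/2 < 1%
    net = _abstract_network([1000.0, 1014.0, 1030.0],
                            [(0, 1, 1e-12), (1, 2, 1e-11)], cfg)
    anns, state = propagate(net, {"n0": "PEPTIDEK"}, 0.0003, 0.005, 0.01)
    assert set(anns) == {"n0", "n1", "n2"}
    assert anns["n1"].n_steps == 1 and anns["n2"].n_steps == 2
    expected = (step_fdr(0.0003, 0.005, 1) + step_fdr(0.0003, 0.005, 2)) / 2
    assert state.aggregate_fdr == pytest.approx(expected, abs=1e-12)
    assert state.id_k == [1, 1, 1]


def test_path_propagation_halts_when_budget_exceeded(cfg):
    # with r = 0.008 the second step would push the aggregate past 1%
    net = _abstract_network([1000.0, 1014.0, 1030.0],
                            [(0, 1, 1e-12), (1, 2, 1e-11)], cfg)
    anns, state = propagate(net, {"n0": "PEPTIDEK"}, 0.0003, 0.008, 0.01)
    assert set(anns) == {"n0", "n1"}
    assert step_fdr(0.0003, 0.008, 1) <= 0.01
    assert (step_fdr(0.0003, 0.008, 1) + step_fdr(0.0003, 0.008, 2)) / 2 > 0.01


def test_star_admits_all_or_nothing(cfg):
    edges = [(0, j, 1e-12 * j) for j in range(1, 4)]
    net = _abstract_network([1000.0, 1014.0, 1030.0, 1044.0], edges, cfg)
    anns, _ = propagate(net, {"n0": "PEPTIDEK"}, 0.0003, 0.005, 0.01)
    assert len(anns) == 4  # FDR1 = 0.0053 <= 1% for every leaf
    anns2, _ = propagate(net, {"n0": "PEPTIDEK"}, 0.0003, 0.02, 0.01)
    assert set(anns2) == {"n0"}  # FDR1 = 0.0203 > 1%


def test_annotation_arrives_through_lowest_p_edge(cfg):
    # n2 is adjacent to both seeds; the lower-p edge wins
    net = _abstract_network([1000.0, 1050.0, 1014.0],
                            [(0, 2, 1e-12), (1, 2, 1e-10)], cfg)
    anns, _ = propagate(net, {"n0": "AAAK", "n1": "CCCK"}, 0.0003, 0.005, 0.01)
    assert anns["n2"].parent == "n0"
    assert anns["n2"].via_edge == ("n0", "n2")


def test_seed_on_unknown_node_is_skipped(cfg, caplog):
    net = _abstract_network([1000.0, 1014.0], [(0, 1, 1e-12)], cfg)
    with caplog.at_level("WARNING", logger="specnet"):
        anns, _ = propagate(net, {"ghost": "AAAK", "n0": "CCCK"},
                            0.0003, 0.005, 0.01)
    assert "ghost" not in anns
    assert set(anns) == {"n0", "n1"}


def test_propagation_is_deterministic(cfg):
    rng = np.random.default_rng(4)
    masses = rng.uniform(900, 1100, size=15)
    edge_list = []
    for _ in range(25):
        i, j = rng.choice(15, size=2, replace=False)
        edge_list.append((int(min(i, j)), int(max(i, j)),
                          float(rng.uniform(1e-15, 1e-9))))
    net = _abstract_network(masses, edge_list, cfg)
    runs = [annotations_table(propagate(net, {"n0": "AAAK", "n5": "CCCK"},
                                        0.0003, 0.005, 0.05)[0])
            for _ in range(2)]
    assert runs[0].equals(runs[1])


# ---------------------------------------------------------------- localization

def test_localize_modification_site_exactly(cfg):
    seq, offs = chem.parse_peptide("PEPT+15.99492IDEK")
    target = theoretical_prm("t", chem.peptide_mass(seq, offs),
                             chem.prefix_masses(seq, offs))
    pep, site, score, kind = localize_mod("PEPTIDEK", 15.99492, target, cfg)
    assert kind == "modified"
    assert site == 3
    assert pep == "PEPT+15.99492IDEK"
    assert score == pytest.approx(target.total_score)


@pytest.mark.parametrize("site", [0, 4, 7])
def test_localize_scans_all_sites(site, cfg):
    base = "GASPVTLNDQK"
    seq = base
    offs = np.zeros(len(seq))
    offs[site] = 42.01057
    target = theoretical_prm("t", chem.peptide_mass(seq, offs),
                             chem.prefix_masses(seq, offs))
    _, found, _, kind = localize_mod(base, 42.01057, target, cfg)
    assert kind == "modified"
    assert found == site


def test_localize_suffix_truncation(cfg):
    target = theoretical_prm("t", chem.peptide_mass("PEPTID"),
                             chem.prefix_masses("PEPTID"))
    delta = -(chem.RESIDUE_MASS["E"] + chem.RESIDUE_MASS["K"])
    pep, site, _, kind = localize_mod("PEPTIDEK", delta, target, cfg)
    assert kind == "truncated"
    assert pep == "PEPTID"
    assert site is None


def test_localize_prefix_truncation(cfg):
    target = theoretical_prm("t", chem.peptide_mass("PTIDEK"),
                             chem.prefix_masses("PTIDEK"))
    delta = -(chem.RESIDUE_MASS["P"] + chem.RESIDUE_MASS["E"])
    pep, _, _, kind = localize_mod("PEPTIDEK", delta, target, cfg)
    assert kind == "truncated"
    assert pep == "PTIDEK"


def test_localize_truncation_strips_boundary_modification(cfg):
    # the truncated form lost both its first two residues and the
    # modification that sat on the retained boundary residue
    target = theoretical_prm("t", chem.peptide_mass("NYSTTDITK"),
                             chem.prefix_masses("NYSTTDITK"))
    delta = -(chem.RESIDUE_MASS["V"] + chem.RESIDUE_MASS["H"] + 15.99492)
    pep, _, _, kind = localize_mod("VHN+15.99492YSTTDITK", delta, target, cfg)
    assert kind == "truncated"
    assert pep == "NYSTTDITK"


def test_localize_zero_delta_is_identity(cfg):
    pep, site, _, kind = localize_mod("PEPTIDEK", 0.0, None, cfg)
    assert (pep, site, kind) == ("PEPTIDEK", None, "identity")


def test_localize_unsupported_delta_attaches_nterminally(cfg):
    # target spectrum shares no masses with any candidate ladder
    target = theoretical_prm("t", 5000.0, np.array([4000.0, 4500.0]))
    pep, site, _, kind = localize_mod("PEPTIDEK", 42.01057, target, cfg)
    assert kind == "unlocalized"
    assert site is None
    assert pep.startswith("P+42.01057")


def test_localize_rejects_oversized_delta(cfg):
    with pytest.raises(ValueError):
        localize_mod("PEPTIDEK", 500.0, None, cfg)


def test_two_step_propagation_localizes_both_modifications(cfg, rng):
    # seed (unmodified) - singly modified - doubly modified; the second
    # site is reached only through the intermediate spectrum
    base = "GASPVTLNDQK"
    single = "GASP+15.99492VTLNDQK"
    double = "GASP+15.99492VTLND+42.01057QK"
    spectra = {sid: spectrum_from_peptide(pep, sid, "sp", rng,
                                          noise_peak_fraction=0.0)
               for sid, pep in
               (("s:0", base), ("s:1", single), ("s:2", double))}
    prms = {sid: to_prm(s, cfg) for sid, s in spectra.items()}
    nodes = {sid: NetworkNode(sid, s.precursor_mass, "sp")
             for sid, s in spectra.items()}
    from specnet.gf import HistogramCache, score_pair
    cache = HistogramCache(cfg)
    edges = [score_pair(prms["s:0"], prms["s:1"], cfg, cache),
             score_pair(prms["s:1"], prms["s:2"], cfg, cache)]
    net = build_network(edges, nodes, None, cfg)
    anns, _ = propagate(net, {"s:0": base}, 0.0003, 0.005, 0.01, prms, cfg)
    assert anns["s:1"].peptide == single
    assert anns["s:2"].peptide == double
    assert anns["s:2"].n_steps == 2
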