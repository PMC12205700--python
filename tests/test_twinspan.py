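"""Pseudospecies expansion, CA axis, divisive classification, fidelity."""

import math

import numpy as np
import pandas as pd
import pytest

from phytoind import (
    ReleveSet,
    ca_axis1,
    fidelity,
    make_pseudospecies,
    synoptic_table,
    twinspan,
)
from phytoind.twinspan import _phi


# --- pseudospecies ----------------------------------------------------------


def _single_plot_rs(cover):
    df = pd.DataFrame({"Sp a": [cover], "Other sp": [1.0]}, index=["p1"])
    df.index.name = "plot_id"
    return ReleveSet(df)


def test_pseudospecies_threshold_rule():
    psm = make_pseudospecies(_single_plot_rs(7.0))
    cols = [c for c in psm.binary.columns if c.startswith("Sp a")]
    assert sorted(cols) == ["Sp a|0", "Sp a|2", "Sp a|5"]


def test_low_cover_level0_only():
    psm = make_pseudospecies(_single_plot_rs(0.5))
    cols = [c for c in psm.binary.columns if c.startswith("Sp a")]
    assert cols == ["Sp a|0"]


def test_nesting_invariant(synthetic_survey):
    """Presence at a cut level implies presence at every lower level."""
    _, rs, _ = synthetic_survey
    psm = make_pseudospecies(rs)
    cuts = psm.cut_levels
    for sp in rs.species[:20]:
        prev = None
        for cut in cuts:
            name = f"{sp}|{cut:g}"
            if name not in psm.binary.columns:
                continue
            col = psm.binary[name].to_numpy(bool)
            if prev is not None:
                assert (col <= prev).all()
            prev = col


def test_column_count_recount_oracle(synthetic_survey):
    """Total columns = brute-force per-(species, cut) recount."""
    _, rs, _ = synthetic_survey
    psm = make_pseudospecies(rs)
    expected = 0
    for sp in rs.species:
        col = rs.covers[sp].dropna()
        for cut in psm.cut_levels:
            if (col >= cut).any() if cut > 0 else len(col) > 0:
                expected += 1
    assert psm.binary.shape[1] == expected


def test_bad_cut_levels_rejected(synthetic_survey):
    _, rs, _ = synthetic_survey
    for cuts in [(2.0, 5.0), (0.0, 5.0, 5.0), (0.0, 10.0, 5.0)]:
        with pytest.raises(ValueError):
            make_pseudospecies(rs, cuts)


# --- correspondence analysis ------------------------------------------------


def _dense_ca_eig1(a: np.ndarray) -> float:
    """Oracle: second eigenvalue of the symmetrised CA operator."""
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    keep = c > 0
    a = a[:, keep]
    c = c[keep]
    s = np.diag(r**-0.5) @ a @ np.diag(c**-1.0) @ a.T @ np.diag(r**-0.5)
    w = np.sort(np.linalg.eigvalsh(s))[::-1]
    return float(w[1])


@pytest.mark.parametrize("shape,seed", [((8, 12), 0), ((15, 25), 1), ((20, 30), 2)])
def test_power_iteration_matches_dense_eigensolver(shape, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random(shape) < 0.35).astype(float)
    a[a.sum(axis=1) == 0, 0] = 1  # no empty rows
    df = pd.DataFrame(a, index=[f"p{i}" for i in range(shape[0])],
                      columns=[f"s{j}" for j in range(shape[1])])
    _, eig = ca_axis1(df)
    assert eig == pytest.approx(_dense_ca_eig1(a), abs=1e-8)


def test_ca_rejects_empty_plot():
    df = pd.DataFrame([[1, 0], [0, 0]], index=["p1", "p2"], columns=["a", "b"])
    with pytest.raises(ValueError, match="p2"):
        ca_axis1(df)


# --- twinspan ---------------------------------------------------------------


def test_two_blocks_first_division_exact(two_block_releves):
    psm = make_pseudospecies(two_block_releves)
    tree = twinspan(psm)
    root = tree.root
    assert not root.is_leaf
    neg = set(root.negative.plot_ids)
    pos = set(root.positive.plot_ids)
    blocks = {frozenset(p for p in psm.plot_ids if p.startswith("a")),
              frozenset(p for p in psm.plot_ids if p.startswith("b"))}
    assert {frozenset(neg), frozenset(pos)} == blocks


def test_single_plot_is_leaf():
    df = pd.DataFrame({"Sp a": [5.0]}, index=["p1"])
    df.index.name = "plot_id"
    tree = twinspan(make_pseudospecies(ReleveSet(df)))
    assert tree.root.is_leaf
    assert tree.n_groups == 1


def test_partition_invariant_under_plot_permutation(synthetic_survey):
    _, rs, _ = synthetic_survey
    tree1 = twinspan(make_pseudospecies(rs))
    rng = np.random.default_rng(0)
    perm = rng.permutation(rs.covers.index)
    rs2 = ReleveSet(rs.covers.loc[perm], rs.plots.loc[perm])
    tree2 = twinspan(make_pseudospecies(rs2))
    part1 = {frozenset(l.plot_ids) for l in tree1.root.leaves()}
    part2 = {frozenset(l.plot_ids) for l in tree2.root.leaves()}
    assert part1 == part2


def test_twinspan_deterministic(synthetic_survey):
    _, rs, _ = synthetic_survey
    t1 = twinspan(make_pseudospecies(rs))
    t2 = twinspan(make_pseudospecies(rs))
    assert t1.to_json() == t2.to_json()


def test_division_eigenvalues_in_unit_interval(synthetic_survey):
    _, rs, _ = synthetic_survey
    tree = twinspan(make_pseudospecies(rs))

    def walk(node):
        if node.is_leaf:
            return
        assert 0 < node.eigenvalue < 1
        assert 1 <= len(node.indicators) <= 5
        assert set(node.negative.plot_ids).isdisjoint(node.positive.plot_ids)
        assert set(node.negative.plot_ids) | set(node.positive.plot_ids) == set(
            node.plot_ids
        )
        walk(node.negative)
        walk(node.positive)

    walk(tree.root)
    leaves = tree.root.leaves()
    all_plots = [p for l in leaves for p in l.plot_ids]
    assert sorted(all_plots) == sorted(rs.plot_ids)


def test_degenerate_matrix_rejected():
    binary = pd.DataFrame([[1, 1], [0, 0], [1, 0]],
                          index=["p1", "p2", "p3"], columns=["a", "b"])
    from phytoind.twinspan import PseudospeciesMatrix

    psm = PseudospeciesMatrix(binary, (0.0,))
    with pytest.raises(ValueError, match="p2"):
        twinspan(psm)


# --- fidelity ---------------------------------------------------------------


def test_phi_hand_value():
    # N=20, N_p=10, n=5, n_p=5 -> 50 / sqrt(7500)
    assert _phi(20, 10, 5, 5) == pytest.approx(50 / math.sqrt(7500))


def _presence_from_dict(d, n_plots):
    plots = [f"p{i}" for i in range(n_plots)]
    df = pd.DataFrame(False, index=plots, columns=sorted(d))
    for sp, idxs in d.items():
        df.loc[[f"p{i}" for i in idxs], sp] = True
    return df


def test_ubiquitous_species_phi_zero():
    pres = _presence_from_dict({"Everywhere sp": range(10), "Other sp": [0]}, 10)
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=pres.index)
    fid = fidelity(pres, groups, equalize=False)
    row = fid[(fid.species == "Everywhere sp") & (fid.group == "A")].iloc[0]
    assert row.phi == pytest.approx(0.0, abs=1e-12)


def test_perfect_indicator_equalized_phi_one():
    pres = _presence_from_dict({"Perfect sp": [0, 1, 2], "Other sp": range(10)}, 10)
    groups = pd.Series(["A"] * 3 + ["B"] * 7, index=pres.index)
    fid = fidelity(pres, groups, equalize=True)
    row = fid[(fid.species == "Perfect sp") & (fid.group == "A")].iloc[0]
    assert row.phi == pytest.approx(1.0)


def test_phi_sign_flips_on_group_complement():
    rng = np.random.default_rng(3)
    pres = pd.DataFrame(rng.random((20, 6)) < 0.4,
                        index=[f"p{i}" for i in range(20)],
                        columns=[f"s{j}" for j in range(6)])
    pres.iloc[0] = True  # avoid empty species/plot edge cases
    groups = pd.Series(["A"] * 8 + ["B"] * 12, index=pres.index)
    fid = fidelity(pres, groups, equalize=False).set_index(["species", "group"])
    for sp in pres.columns:
        a, b = fid.loc[(sp, "A"), "phi"], fid.loc[(sp, "B"), "phi"]
        if not (np.isnan(a) or np.isnan(b)):
            assert a == pytest.approx(-b, abs=1e-12)


def test_fidelity_counts_consistent(synthetic_survey):
    com, rs, labels = synthetic_survey
    fid = fidelity(rs, labels)
    assert (fid.n_p <= np.minimum(fid.n, fid.N_p)).all()
    assert (fid.phi.dropna() >= -1).all() and (fid.phi.dropna() <= 1).all()
    assert ((fid.p_value >= 0) & (fid.p_value <= 1)).all()


# --- synoptic table ---------------------------------------------------------


def test_synoptic_percentages():
    pres = _presence_from_dict({"Sp a": [0, 1, 2], "Sp b": range(10)}, 10)
    groups = pd.Series(["A"] * 10, index=pres.index)
    groups.iloc[5:] = "B"
    fid = fidelity(pres, groups)
    pct, _ = synoptic_table(pres, groups, fid)
    assert pct.loc["Sp a", "A"] == pytest.approx(60.0)  # 3 of 5
    assert pct.loc["Sp b", "B"] == pytest.approx(100.0)


def test_diagnostic_requires_both_thresholds():
    fid = pd.DataFrame(
        [
            {"species": "Sp a", "group": "A", "N": 20, "N_p": 10, "n": 5, "n_p": 5,
             "phi": 0.6, "p_value": 0.2},
            {"species": "Sp b", "group": "A", "N": 20, "N_p": 10, "n": 8, "n_p": 8,
             "phi": 0.8, "p_value": 0.001},
        ]
    )
    pres = _presence_from_dict({"Sp a": [0], "Sp b": [0]}, 20)
    groups = pd.Series(["A"] * 10 + ["B"] * 10, index=pres.index)
    _, diag = synoptic_table(pres, groups, fid)
    assert not diag.loc["Sp a", "diagnostic"]  # p too large
    assert diag.loc["Sp b", "diagnostic"]


def test_planted_indicators_recovered(synthetic_survey):
    com, rs, labels = synthetic_survey
    fid = fidelity(rs, labels)
    _, diag = synoptic_table(rs, labels, fid)
    planted = com.species_meta[com.species_meta.is_indicator]
    hits = sum(
        1
        for sp, row in planted.iterrows()
        if sp in diag.index
        and diag.loc[sp, "diagnostic"]
        and diag.loc[sp, "best_group"] == row.association
    )
    assert hits / len(planted) >= 0.8
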