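"""Window classification rules, scan/oracle equivalence, count table."""

import numpy as np
import pytest

from catrace.segment_classify import (ClassifyParams, count_table, is_etb,
                                      is_fd, is_fh, is_netb, is_ns, scan,
                                      strip_gly_pro)
from catrace.structure_io import CAlphaChain, annotate_bonds
from catrace.synthetic_data import (hairpin_design, make_coil, make_hairpin,
                                    make_helix)
from catrace.virtual_geometry import compute_geometry, rebuild_chain


def chain_from_theta(theta, gamma=None, helix=None, sheet=None):
    """Chain with a prescribed theta profile (1-based theta_2..)."""
    nres = len(theta) + 2
    if gamma is None:
        gamma = [60.0] * (nres - 3)
    coords = rebuild_chain([3.8] * (nres - 1), theta, gamma)
    ch = CAlphaChain("A", np.arange(1, nres + 1), ["ALA"] * nres, coords)
    if helix is not None:
        ch.helix_flag[helix] = True
    if sheet is not None:
        ch.sheet_flag[sheet] = True
    return annotate_bonds(ch), compute_geometry(coords)


P120 = ClassifyParams(theta_ext=120.0)
P135 = ClassifyParams(theta_ext=135.0)


class TestPredicates:
    @pytest.mark.parametrize("theta,params,expected", [
        ([95, 130, 95], P120, True),
        ([95, 130, 95], P135, False),
        ([99, 125, 118, 80], P120, False),     # one inner theta <= 120
    ])
    def test_is_etb(self, theta, params, expected):
        _, geom = chain_from_theta(theta)
        assert is_etb(geom, 1, len(theta) - 1, params) is expected

    def test_is_netb_and_helix_veto(self):
        ch, geom = chain_from_theta([95, 110, 95])
        assert is_netb(geom, ch, 1, 2, P120)
        ch2, geom2 = chain_from_theta([95, 110, 95], helix=[2])
        assert not is_netb(geom2, ch2, 1, 2, P120)

    def test_etb_netb_exclusive_at_120(self):
        for inner in (110.0, 120.0, 121.0, 150.0):
            ch, geom = chain_from_theta([95, inner, 95])
            assert not (is_etb(geom, 1, 2, P120)
                        and is_netb(geom, ch, 1, 2, P120))

    @pytest.mark.parametrize("theta,expected", [
        ([140, 90, 92, 150], True),            # terminals unconstrained
        ([90, 90, 105, 90], False),            # inner 105 >= 100
    ])
    def test_is_fd(self, theta, expected):
        _, geom = chain_from_theta(theta)
        assert is_fd(geom, 1, 3, ClassifyParams()) is expected

    def test_fd_etb_exclusive(self):
        for inner in (80.0, 99.0, 130.0):
            _, geom = chain_from_theta([95.0, inner, 95.0])
            assert not (is_fd(geom, 1, 2, P120) and is_etb(geom, 1, 2, P120))

    def test_is_fh_gamma_band_or_helix_records(self):
        ch, geom = chain_from_theta([120, 90, 90, 120], gamma=[50, 50, 50])
        assert is_fh(geom, ch, 1, 3, ClassifyParams())
        ch2, geom2 = chain_from_theta([120, 90, 90, 120],
                                      gamma=[50, 100, 50])
        assert not is_fh(geom2, ch2, 1, 3, ClassifyParams())
        ch3, geom3 = chain_from_theta([120, 90, 90, 120],
                                      gamma=[50, 100, 50],
                                      helix=slice(1, 6))
        assert is_fh(geom3, ch3, 1, 3, ClassifyParams())

    def test_fh_implies_fd(self, rng):
        for _ in range(50):
            theta = rng.uniform(60, 170, 4)
            ch, geom = chain_from_theta(theta, gamma=rng.uniform(0, 70, 3))
            if is_fh(geom, ch, 1, 3, ClassifyParams()):
                assert is_fd(geom, 1, 3, ClassifyParams())

    def test_is_ns(self):
        ch, _ = chain_from_theta([95, 110, 95])
        assert is_ns(ch, 1, 2)
        ch2, _ = chain_from_theta([95, 110, 95], sheet=[3])
        assert not is_ns(ch2, 1, 2)


def brute_force_scan(chain, geom, kind, n, params):
    """Independent oracle: direct predicate evaluation at every start."""
    hits = []
    flagged = chain.flagged_bonds()
    for k in range(1, geom.nres - n - 1):
        if flagged[k - 1 : k + n + 1].any():
            continue
        tf = geom.theta[k + 1]
        tl = geom.theta[k + n + 1]
        ti = geom.theta[k + 2 : k + n + 1]
        g = geom.gamma[k + 1 : k + n + 1]
        if np.isnan([tf, tl]).any() or np.isnan(ti).any() or np.isnan(g).any():
            continue
        hflags = chain.helix_flag[k : k + n + 1]
        sflags = chain.sheet_flag
        ok = {
            "ETB": tf < 100 and tl < 100 and (ti > params.theta_ext).all(),
            "NETB": tf < 100 and tl < 100 and (ti <= 120).all()
                    and not hflags.any(),
            "FD": (ti < 100).all(),
            "FH": (ti < 100).all() and (((g >= 0) & (g <= 70)).all()
                                        or hflags.all()),
            "NS": not (chain.helix_flag[k - 1 : k + n + 2].any()
                       or sflags[k - 1 : k + n + 2].any()),
        }[kind]
        if ok:
            hits.append(k)
    return hits


class TestScan:
    def test_hairpin_single_designed_etb(self):
        ch = make_hairpin(1)
        geom = compute_geometry(ch.coords)
        k, n = hairpin_design(1)
        segs = scan(ch, geom, "ETB", n, P120)
        assert [(s.k, s.n) for s in segs] == [(k, n)]
        # shifted windows fail the definition
        for other_n in (3, 4):
            assert scan(ch, geom, "ETB", other_n, P120) == []

    def test_hairpin_lower_cutoff_flips_to_netb(self):
        ch = make_hairpin(1, theta_ext_val=110.0)
        geom = compute_geometry(ch.coords)
        assert scan(ch, geom, "ETB", 2, P120) == []
        segs = scan(ch, geom, "NETB", 2, P120)
        assert [(s.k, s.n) for s in segs] == [hairpin_design(1)]

    def test_helix_fd_windows_match_enumeration(self):
        ch = make_helix(20)
        geom = compute_geometry(ch.coords)
        segs = scan(ch, geom, "FD", 2, P120)
        expected = brute_force_scan(ch, geom, "FD", 2, P120)
        assert [s.k for s in segs] == expected
        assert len(segs) == geom.nres - 2 - 2   # every admissible start

    def test_short_chain_empty(self):
        ch = make_helix(4)
        geom = compute_geometry(ch.coords)
        assert scan(ch, geom, "FD", 2, ClassifyParams()) == []

    @pytest.mark.parametrize("kind", ["ETB", "NETB", "FD", "FH", "NS"])
    def test_oracle_equivalence_random_chains(self, kind, rng):
        for trial in range(30):
            ch = make_coil(int(rng.integers(8, 30)), seed=trial)
            if rng.random() < 0.5:
                ch.helix_flag[rng.random(ch.nres) < 0.3] = True
                ch.sheet_flag[rng.random(ch.nres) < 0.2] = True
            geom = compute_geometry(ch.coords)
            for n in (2, 3):
                got = [s.k for s in scan(ch, geom, kind, n, P120)]
                assert got == brute_force_scan(ch, geom, kind, n, P120)

    def test_cis_bond_excludes_window(self):
        ch = make_hairpin(1)
        ch.cis_flag[4] = True               # bond inside the ETB window
        geom = compute_geometry(ch.coords)
        assert scan(ch, geom, "ETB", 2, P120) == []

    def test_etb_monotone_in_theta_ext(self, rng):
        for trial in range(10):
            ch = make_coil(25, seed=100 + trial)
            geom = compute_geometry(ch.coords)
            n120 = len(scan(ch, geom, "ETB", 2, P120))
            n135 = len(scan(ch, geom, "ETB", 2, P135))
            assert n135 <= n120


class TestStripGlyPro:
    def test_removal_and_idempotence(self):
        ch = make_hairpin(1)
        ch.residue_names[4] = "GLY"
        geom = compute_geometry(ch.coords)
        segs = scan(ch, geom, "ETB", 2, P120)
        assert segs and segs[0].contains_gly_pro
        assert strip_gly_pro(segs) == []
        kept = scan(make_hairpin(1), compute_geometry(make_hairpin(1).coords),
                    "ETB", 2, P120)
        assert strip_gly_pro(strip_gly_pro(kept)) == strip_gly_pro(kept)


class TestCountTable:
    def test_empty_dataset_all_zero(self):
        table = count_table([])
        assert (table.values == 0).all()

    def test_helix_counts_match_enumeration(self):
        ch = make_helix(20)
        geom = compute_geometry(ch.coords)
        table = count_table([ch])
        assert table.loc[("ETB", "2"), "all"] == 0
        fd2 = len(brute_force_scan(ch, geom, "FD", 2, ClassifyParams()))
        assert table.loc[("FD", "2"), "all"] == fd2
        fd_mid = sum(len(brute_force_scan(ch, geom, "FD", n,
                                          ClassifyParams()))
                     for n in range(3, 18))
        assert table.loc[("FD", "[3,20]"), "all"] == fd_mid

    def test_gly_pro_column_monotone(self, rng):
        chains = []
        for trial in range(5):
            ch = make_coil(20, seed=trial)
            names = list(ch.residue_names)
            for i in np.where(rng.random(20) < 0.2)[0]:
                names[i] = "GLY" if rng.random() < 0.5 else "PRO"
            ch.residue_names = names
            chains.append(ch)
        table = count_table(chains)
        assert (table["gly_pro_excluded"] <= table["all"]).all()
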