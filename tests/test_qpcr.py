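import numpy as np
import pandas as pd
import pytest

from ifxpanel.io import CtMatrix, DataError, Metadata, SampleMeta
from ifxpanel.qpcr import (
    ddct_contrast,
    delta_ct,
    fold_regulation_of,
    select_de_genes,
)


def _ct(data: dict, genes, hk, imputed=None):
    df = pd.DataFrame(data, index=genes, dtype=float)
    mask = None
    if imputed is not None:
        mask = pd.DataFrame(False, index=df.index, columns=df.columns)
        for g, s in imputed:
            mask.at[g, s] = True
    return CtMatrix(df, hk, imputed=mask)


def _meta(n_a=3, n_b=3):
    rows = [
        SampleMeta(f"A{i}", f"pa{i}", "CD", "pre", "R") for i in range(n_a)
    ] + [
        SampleMeta(f"B{i}", f"pb{i}", "CD", "pre", "NONR") for i in range(n_b)
    ]
    return Metadata(rows)


class TestDeltaCt:
    def test_subtracts_mean_housekeeping(self):
        # housekeeping Ct (19, 20, 21, 20, 20) -> mean 20; gene 25 -> dCt 5
        genes = ["TNF", "HK1", "HK2", "HK3", "HK4", "HK5"]
        ct = _ct({"S1": [25, 19, 20, 21, 20, 20]}, genes,
                 ("HK1", "HK2", "HK3", "HK4", "HK5"))
        dct = delta_ct(ct)
        assert dct.data.at["TNF", "S1"] == pytest.approx(5.0)
        assert dct.gene_ids == ["TNF"]  # housekeeping rows excluded

    def test_gene_equal_to_reference_gives_zero(self):
        ct = _ct({"S1": [20.0, 20.0]}, ["TNF", "ACTB"], ("ACTB",))
        assert delta_ct(ct).data.at["TNF", "S1"] == 0.0

    def test_three_gene_toy_matches_hand_computation(self):
        # reference per sample: S1 mean(20,22)=21; S2 mean(19,21)=20
        genes = ["G1", "G2", "G3", "HK1", "HK2"]
        ct = _ct(
            {"S1": [25, 21, 30, 20, 22], "S2": [24, 18, 31, 19, 21]},
            genes, ("HK1", "HK2"),
        )
        dct = delta_ct(ct)
        expected = pd.DataFrame(
            {"S1": [4.0, 0.0, 9.0], "S2": [4.0, -2.0, 11.0]},
            index=["G1", "G2", "G3"],
        )
        pd.testing.assert_frame_equal(dct.data, expected)

    def test_undetermined_housekeeping_errors(self):
        ct = _ct({"S1": [25, 35]}, ["TNF", "ACTB"], ("ACTB",),
                 imputed=[("ACTB", "S1")])
        with pytest.raises(DataError, match="housekeeping"):
            delta_ct(ct)


class TestDdctContrast:
    def _records(self, a_vals, b_vals, gene_noise=0.0, seed=0):
        """Build a contrast where gene G has the given dCt values per group."""
        rng = np.random.default_rng(seed)
        n_a, n_b = len(a_vals), len(b_vals)
        meta = _meta(n_a, n_b)
        cols = {}
        for i, v in enumerate(a_vals):
            cols[f"A{i}"] = [20 + v + gene_noise * rng.normal(), 20.0]
        for i, v in enumerate(b_vals):
            cols[f"B{i}"] = [20 + v + gene_noise * rng.normal(), 20.0]
        ct = CtMatrix(pd.DataFrame(cols, index=["G", "ACTB"]), ("ACTB",))
        return ddct_contrast(delta_ct(ct), meta, "CD_PRE_R", "CD_PRE_NONR")

    def test_fold_change_formula(self):
        # mean dCt a=4, b=5 -> ddCt = -1 -> FC 2, fold regulation +2
        (rec,) = self._records([4, 4, 4], [5, 5, 5])
        assert rec.ddct == pytest.approx(-1.0)
        assert rec.fold_change == pytest.approx(2.0)
        assert rec.fold_regulation == pytest.approx(2.0)
        assert rec.direction == "up_in_a"

    def test_identity_contrast(self):
        (rec,) = self._records([3, 4, 5], [3, 4, 5])
        assert rec.fold_change == pytest.approx(1.0)
        assert rec.fold_regulation == pytest.approx(1.0)

    def test_sign_convention_downregulation(self):
        # ddCt = +2 -> FC 0.25 -> fold regulation -4
        (rec,) = self._records([6, 6, 6], [4, 4, 4])
        assert rec.fold_change == pytest.approx(0.25)
        assert rec.fold_regulation == pytest.approx(-4.0)
        assert rec.direction == "down_in_a"

    def test_antisymmetry_and_fc_inverse(self):
        rng = np.random.default_rng(5)
        a = rng.normal(4, 1, 5).tolist()
        b = rng.normal(6, 1, 5).tolist()
        meta = _meta(5, 5)
        cols = {f"A{i}": [20 + v, 20.0] for i, v in enumerate(a)}
        cols.update({f"B{i}": [20 + v, 20.0] for i, v in enumerate(b)})
        ct = CtMatrix(pd.DataFrame(cols, index=["G", "ACTB"]), ("ACTB",))
        dct = delta_ct(ct)
        (fwd,) = ddct_contrast(dct, meta, "CD_PRE_R", "CD_PRE_NONR")
        (rev,) = ddct_contrast(dct, meta, "CD_PRE_NONR", "CD_PRE_R")
        assert fwd.ddct == pytest.approx(-rev.ddct)
        assert fwd.fold_regulation == pytest.approx(-rev.fold_regulation)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.fold_change * 2.0**fwd.ddct == pytest.approx(1.0, abs=1e-12)

    def test_requires_two_samples_per_group(self):
        meta = _meta(1, 3)
        cols = {"A0": [24.0, 20.0]}
        cols.update({f"B{i}": [25.0, 20.0] for i in range(3)})
        ct = CtMatrix(pd.DataFrame(cols, index=["G", "ACTB"]), ("ACTB",))
        with pytest.raises(DataError, match="fewer than 2"):
            ddct_contrast(delta_ct(ct), meta, "CD_PRE_R", "CD_PRE_NONR")

    def test_low_confidence_flag_on_majority_imputed(self):
        meta = _meta(3, 3)
        cols = {f"A{i}": [35.0, 20.0] for i in range(3)}
        cols.update({f"B{i}": [25.0 + i * 0.1, 20.0] for i in range(3)})
        mask = pd.DataFrame(False, index=["G", "ACTB"], columns=cols)
        for i in range(2):  # 2/3 imputed in group a
            mask.at["G", f"A{i}"] = True
        ct = CtMatrix(pd.DataFrame(cols, index=["G", "ACTB"]), ("ACTB",),
                      imputed=mask)
        (rec,) = ddct_contrast(delta_ct(ct), meta, "CD_PRE_R", "CD_PRE_NONR")
        assert rec.low_confidence


class TestSelection:
    def _rec(self, fr, p):
        from ifxpanel.qpcr import DEGRecord

        fc = fr if fr >= 1 else -1.0 / fr
        return DEGRecord(
            gene_id=f"g{fr}_{p}", group_a="a", group_b="b",
            ddct=-np.log2(fc), fold_change=fc,
            fold_regulation=fr, p_value=p, p_bh=p,
            direction="up_in_a" if fr >= 1 else "down_in_a",
        )

    def test_boundary_fold_kept_strict_p(self):
        sel = select_de_genes([self._rec(-2.0, 0.049)], 2.0, 0.05)
        assert len(sel.down) == 1
        sel = select_de_genes([self._rec(-2.0, 0.05)], 2.0, 0.05)  # p not < alpha
        assert not sel.genes

    def test_subthreshold_fold_dropped(self):
        sel = select_de_genes([self._rec(1.9, 0.001)], 2.0, 0.05)
        assert not sel.genes

    def test_panel_eligible_fold(self):
        sel = select_de_genes([self._rec(16.0, 0.01)], 15.0, 0.05)
        assert sel.up and not sel.down


def test_fold_regulation_helper():
    assert fold_regulation_of(2.0) == 2.0
    assert fold_regulation_of(0.25) == -4.0
    assert fold_regulation_of(1.0) == 1.0
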