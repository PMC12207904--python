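import numpy as np
import pandas as pd
import pytest

from domstat import (PeakTable, compute_icer, compute_mer,
                     icer_temperature_regression, run_icer_protocol,
                     split_dataset)
from domstat.synthetic import StudyDesign


@pytest.fixture(scope="module")
def meta():
    return StudyDesign().metadata()


@pytest.fixture(scope="module")
def region_meta(meta):
    return meta[meta["region"] == "subtropical"]


class TestSplit:
    def test_sizes_80_20(self, region_meta):
        mer, icer = split_dataset(region_meta, ratio=0.8, stratify=(), seed=0)
        assert len(mer) == 14 and len(icer) == 4  # round(0.8 * 18) = 14

    def test_disjoint_exhaustive(self, region_meta):
        mer, icer = split_dataset(region_meta, ratio=0.8, stratify=(), seed=1)
        assert not set(mer) & set(icer)
        assert set(mer) | set(icer) == set(region_meta.index)

    def test_seed_reproducible(self, region_meta):
        a = split_dataset(region_meta, stratify=(), seed=42)
        b = split_dataset(region_meta, stratify=(), seed=42)
        assert a == b

    def test_heldout_spans_gradient(self, region_meta):
        _, icer = split_dataset(region_meta, stratify=(), seed=3)
        temps = region_meta.loc[icer, "temperature"]
        assert temps.nunique() == len(icer)  # round-robin over levels

    def test_degenerate_ratio_rejected(self, region_meta):
        with pytest.raises(ValueError, match="ratio"):
            split_dataset(region_meta, ratio=1.0, stratify=())

    def test_small_stratum_rejected(self, region_meta):
        with pytest.raises(ValueError, match="too small"):
            split_dataset(region_meta.head(3), stratify=())

    def test_region_stratification(self, meta):
        mer, icer = split_dataset(meta, stratify=("region",), seed=0)
        for subset in (mer, icer):
            assert meta.loc[subset, "region"].nunique() == 2


class TestMer:
    def test_perfect_monotone(self, region_meta):
        temps = region_meta["temperature"].astype(float)
        mono = np.exp(0.2 * temps.to_numpy())
        other = np.ones(len(temps))
        pt = PeakTable(pd.DataFrame([mono, other], index=["up", "flat"],
                                    columns=region_meta.index))
        mer = compute_mer(pt, temps, min_occupancy=0.3)
        assert mer.loc["up", "mer"] == pytest.approx(1.0)
        # closure makes the raw-constant molecule decline in relative terms
        assert mer.loc["flat", "mer"] == pytest.approx(-1.0)

    def test_constant_relative_abundance_dropped(self, region_meta):
        temps = region_meta["temperature"].astype(float)
        mono = np.exp(0.2 * temps.to_numpy())
        pt = PeakTable(pd.DataFrame([mono, mono], index=["a", "b"],
                                    columns=region_meta.index))
        mer = compute_mer(pt, temps)  # both have constant share 0.5
        assert mer.empty

    def test_low_occupancy_excluded(self, region_meta):
        x = np.zeros(len(region_meta))
        x[:2] = 5.0  # present in 2/18 samples
        y = np.linspace(1, 2, len(region_meta))
        pt = PeakTable(pd.DataFrame([x, y], index=["rare", "common"],
                                    columns=region_meta.index))
        mer = compute_mer(pt, region_meta["temperature"].astype(float))
        assert "rare" not in mer.index
        assert "common" in mer.index

    def test_constant_temperature_rejected(self, region_meta):
        sub = region_meta[region_meta["temperature"] == 5]
        pt = PeakTable(pd.DataFrame(np.ones((3, len(sub))),
                                    index=list("abc"), columns=sub.index))
        with pytest.raises(ValueError, match="vary"):
            compute_mer(pt, sub["temperature"].astype(float))

    def test_negating_temperature_negates_mer(self, study):
        meta = study["metadata"]
        sub = meta[meta["region"] == "subtropical"]
        pt = study["peaks"].subset_samples(sub.index)
        plus = compute_mer(pt, sub["temperature"].astype(float))
        minus = compute_mer(pt, -sub["temperature"].astype(float))
        assert np.allclose(plus["mer"], -minus["mer"], equal_nan=True)


class TestIcer:
    def _mer(self, vals, ps=None):
        ids = [f"m{i}" for i in range(len(vals))]
        return pd.DataFrame({"mer": vals,
                             "p": ps if ps is not None else [0.001] * len(vals)},
                            index=ids)

    def test_weighted_mean_arithmetic(self):
        mer = self._mer([0.5, -0.5])
        pt = PeakTable(pd.DataFrame({"s": [0.75, 0.25]}, index=["m0", "m1"]))
        assert compute_icer(pt, mer)["s"] == pytest.approx(0.25)

    def test_all_positive_unit_mers(self):
        mer = self._mer([1.0, 1.0, 1.0])
        pt = PeakTable(pd.DataFrame({"s": [0.2, 0.3, 0.5]},
                                    index=["m0", "m1", "m2"]))
        assert compute_icer(pt, mer)["s"] == pytest.approx(1.0)

    def test_balanced_mers_cancel(self):
        mer = self._mer([0.7, -0.7])
        pt = PeakTable(pd.DataFrame({"s": [1.0, 1.0]}, index=["m0", "m1"]))
        assert compute_icer(pt, mer)["s"] == pytest.approx(0.0)

    def test_insignificant_mers_ignored(self):
        mer = self._mer([0.9, -0.2], ps=[0.001, 0.5])
        pt = PeakTable(pd.DataFrame({"s": [0.5, 0.5]}, index=["m0", "m1"]))
        assert compute_icer(pt, mer)["s"] == pytest.approx(0.9)

    def test_no_contributors_warns_nan(self):
        mer = self._mer([0.9], ps=[0.9])
        pt = PeakTable(pd.DataFrame({"s": [1.0]}, index=["m0"]))
        with pytest.warns(UserWarning, match="no significant"):
            out = compute_icer(pt, mer)
        assert np.isnan(out["s"])

    def test_convex_combination_bounds(self, study):
        meta = study["metadata"]
        sub = meta[meta["region"] == "temperate"]
        pt = study["peaks"].subset_samples(sub.index)
        mer_samples, icer_samples = split_dataset(sub, stratify=(), seed=0)
        mer = compute_mer(pt.subset_samples(mer_samples),
                          sub["temperature"].astype(float))
        icer = compute_icer(pt.subset_samples(icer_samples), mer).dropna()
        sig = mer[mer["p"] < 0.05]["mer"]
        assert (icer >= sig.min() - 1e-12).all()
        assert (icer <= sig.max() + 1e-12).all()


class TestProtocol:
    def test_planted_warming_recovered(self, study):
        res = run_icer_protocol(study["peaks"], study["metadata"],
                                n_repeats=25, seed=9)
        reg = icer_temperature_regression(res, study["metadata"])
        assert (reg["slope"] > 0).all()
        assert (reg["p"] < 0.05).all()

    def test_mer_sign_recovery(self, study):
        truth = study["truth"]
        meta = study["metadata"]
        res = run_icer_protocol(study["peaks"], meta, n_repeats=10, seed=4)
        hits = total = 0
        for region, sets in truth.responders.items():
            mer_r = res.mer_mean[res.mer_mean["region"] == region]["mer_mean"]
            for sign, role in ((1, "accumulating"), (-1, "depleting")):
                vals = mer_r.reindex(sets[role]).dropna()
                hits += (np.sign(vals) == sign).sum()
                total += len(vals)
        assert total > 0
        assert hits / total >= 0.9

    def test_repeat_counts_recorded(self, study):
        res = run_icer_protocol(study["peaks"], study["metadata"],
                                n_repeats=5, seed=1)
        assert res.icer_mean["n_repeats"].sum() > 0
        assert (res.icer_mean["n_repeats"] <= 5).all()
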