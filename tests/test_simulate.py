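"""Synthetic-study generator: planted-truth recovery, noise model,
determinism."""

import filecmp
import pathlib

import numpy as np
import pandas as pd
import pytest

from utrscreen import (
    STUDY_MIRNAS,
    ReporterScreen,
    StudyConfig,
    UnplaceableSiteError,
    UTRSequence,
    find_seed_sites,
    generate_plate,
    generate_study,
    generate_utr,
    pairwise_site_overlap,
)
from utrscreen.screen import replicate_ratios

MIR129 = STUDY_MIRNAS[0]
MIR873 = STUDY_MIRNAS[3]


class TestGenerateUtr:
    def test_planted_site_recovered_exactly(self, rng):
        seq, sites = generate_utr(300, [(MIR129, "8mer", 150)], rng,
                                  screen_mirnas=STUDY_MIRNAS)
        frag = UTRSequence("g", "f", seq)
        found = find_seed_sites(frag, MIR129)
        assert [(s.site_type, s.start, s.end) for s in found] == [
            (s.site_type, s.start, s.end) for s in sites]
        assert found[0].site_type == "8mer"
        assert abs(found[0].start - 150) <= 2

    @pytest.mark.parametrize("stype", ["6mer", "7mer-A1", "7mer-m8", "8mer"])
    def test_planted_type_not_upgraded_or_downgraded(self, rng, stype):
        for _ in range(5):
            seq, _ = generate_utr(200, [(MIR873, stype, 90)], rng)
            found = find_seed_sites(UTRSequence("g", "f", seq), MIR873)
            assert [s.site_type for s in found] == [stype]

    def test_no_planted_no_sites(self, rng):
        for _ in range(10):
            seq, sites = generate_utr(500, [], rng, screen_mirnas=STUDY_MIRNAS)
            assert sites == []
            frag = UTRSequence("g", "f", seq)
            assert all(not find_seed_sites(frag, m) for m in STUDY_MIRNAS)

    def test_two_mirnas_shared_fragment_overlap_count(self, rng):
        seq, _ = generate_utr(400, [(MIR129, "7mer-m8", 100),
                                    (MIR873, "6mer", 250)], rng,
                              screen_mirnas=[MIR129, MIR873])
        frag = UTRSequence("g", "f", seq)
        sets = {m.name: ({"f"} if find_seed_sites(frag, m) else set())
                for m in (MIR129, MIR873)}
        assert pairwise_site_overlap(sets)[(MIR129.name, MIR873.name)] == 1

    def test_overlapping_planted_sites_rejected(self, rng):
        with pytest.raises(UnplaceableSiteError):
            generate_utr(300, [(MIR129, "8mer", 150), (MIR873, "8mer", 153)],
                         rng)

    def test_deterministic(self):
        a, _ = generate_utr(300, [(MIR129, "8mer", 150)],
                            np.random.default_rng(5))
        b, _ = generate_utr(300, [(MIR129, "8mer", 150)],
                            np.random.default_rng(5))
        assert a == b


class TestGeneratePlate:
    def _truth(self, n, mean):
        return pd.DataFrame({
            "construct_id": [f"c{i:04d}" for i in range(n)],
            "mirna": "miR-x",
            "true_mean": mean,
        })

    def test_zero_noise_gives_exact_means(self, rng):
        plates = generate_plate(self._truth(3, 0.75), noise_sd=0.0, rng=rng)
        for cid, grp in plates.groupby("construct_id"):
            rt = replicate_ratios(grp[grp["mirna"] == "miR-x"])
            rc = replicate_ratios(grp[grp["mirna"] == "empty"])
            assert np.allclose(rt / rc, 0.75)
            assert np.allclose(rc, 1.0)

    def test_grand_mean_recovery(self, rng):
        """Pipeline-estimated grand mean ~ true mean (law of large numbers)."""
        plates = generate_plate(self._truth(300, 0.6), noise_sd=0.05, rng=rng)
        res = ReporterScreen.from_plate_table(plates).fit()
        assert res.mti_table["mean_rlu"].mean() == pytest.approx(0.6, abs=0.01)

    def test_same_seed_identical(self):
        t = self._truth(5, 0.8)
        p1 = generate_plate(t, rng=np.random.default_rng(9))
        p2 = generate_plate(t, rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(p1, p2)

    def test_nonpositive_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_plate(self._truth(1, 0.0), rng=rng)


class TestGenerateStudy:
    def test_bundle_consistency(self, small_bundle):
        b = small_bundle
        assert len(b.utrs) == 8
        assert set(b.mti_truth.columns) >= {"construct_id", "gene", "mirna",
                                            "true_mean", "effect_class"}
        # every non-sensor MTI corresponds to a fragment with >= 1 site
        frags = {f"{f.gene}|{f.fragment_id}": f for f in b.fragments}
        by_name = {m.name: m for m in b.mirnas}
        for _, row in b.mti_truth.iterrows():
            if row["effect_class"] == "sensor":
                continue
            frag = frags[row["construct_id"]]
            assert len(find_seed_sites(frag, by_name[row["mirna"]])) == row["n_sites"]

    def test_all_planted_sites_recovered_from_fragments(self, small_bundle):
        b = small_bundle
        by_name = {m.name: m for m in b.mirnas}
        recovered = set()
        for frag in b.fragments:
            for m in b.mirnas:
                for s in find_seed_sites(frag, m):
                    recovered.add((frag.gene, m.name, s.site_type,
                                   s.start + frag.parent_offset - 1,
                                   s.end + frag.parent_offset - 1))
        planted = {(r["gene"], r["mirna"], r["site_type"], r["start"], r["end"])
                   for _, r in b.truth_sites.iterrows()}
        assert planted == recovered

    def test_sensors_present_and_strongly_repressed(self, small_bundle):
        sensors = small_bundle.mti_truth.query("effect_class == 'sensor'")
        assert len(sensors) == len(small_bundle.mirnas)
        assert (sensors["true_mean"] < 0.2).all()

    def test_byte_identical_rerun(self, tmp_path):
        config = StudyConfig(n_genes=3, utr_length_range=(200, 700),
                             rng_seed=7)
        for sub in ("a", "b"):
            generate_study(config).write(tmp_path / sub)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_structures_on_request(self):
        config = StudyConfig(n_genes=2, utr_length_range=(60, 120),
                             fold_structures=True, rng_seed=2)
        bundle = generate_study(config)
        assert bundle.structures
        for frag in bundle.fragments:
            cid = f"{frag.gene}|{frag.fragment_id}"
            assert len(bundle.structures[cid]) == len(frag)
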