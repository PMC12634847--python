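"""The three search modes, scoring, localization and the delta histogram."""

import numpy as np
import pytest

from openhist.pipeline import build_candidates
from openhist.proteolysis import apply_protocol
from openhist.search import (
    PSM,
    SearchConfig,
    closed_search,
    delta_histogram,
    dmo_search,
    open_search,
    score_match,
    write_psm_table,
)
from openhist.spectra import (
    SyntheticParams,
    Spectrum,
    generate_dataset,
    synthesize_spectrum,
    theoretical_fragments,
)

CLEAN = SyntheticParams(detection_prob=1.0, n_noise_peaks=0, mz_jitter_ppm=0.0)


def psm_fingerprint(psms):
    return [
        (p.spectrum_id, p.peptide, p.form.assigned_mods_str(), p.score, p.delta_mass)
        for p in psms
    ]


class TestScoreMatch:
    def test_perfect_spectrum_matches_everything(self, pro_pic, h3_tail_peptide, rng):
        form = apply_protocol(h3_tail_peptide, pro_pic, {})
        s = synthesize_spectrum(form, 2, CLEAN, rng)
        frags = theoretical_fragments(form, (1, 2))
        score, report = score_match(s, frags)
        assert report.matched_b == report.theor_b
        assert report.matched_y == report.theor_y
        assert (report.matched_b + report.matched_y) / (
            report.theor_b + report.theor_y
        ) == 1.0
        assert score > 0

    def test_empty_spectrum_scores_floor(self, pro_pic, h3_tail_peptide):
        form = apply_protocol(h3_tail_peptide, pro_pic, {})
        empty = Spectrum("e", 500.0, 2, np.array([]), np.array([]))
        score, report = score_match(empty, theoretical_fragments(form))
        assert score == 0.0
        assert report.matched_b == report.matched_y == 0

    def test_adding_matching_peak_never_decreases_score(self, pro_pic, rng):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        frags = theoretical_fragments(form, (1,))
        theo = sorted(i.mz for i in frags.primary)
        for _ in range(30):
            k = int(rng.integers(1, len(theo)))
            subset = sorted(rng.choice(theo, size=k, replace=False))
            intens = rng.uniform(1.0, 100.0, size=k)
            order = np.argsort(subset)
            s1 = Spectrum("a", 500.0, 2, np.array(subset)[order], intens[order])
            base, _ = score_match(s1, frags)
            extra = next(m for m in theo if m not in subset)
            mz2 = np.append(s1.mz, extra)
            it2 = np.append(s1.intensity, float(rng.uniform(1.0, 100.0)))
            o2 = np.argsort(mz2)
            s2 = Spectrum("b", 500.0, 2, mz2[o2], it2[o2])
            more, _ = score_match(s2, frags)
            assert more >= base

    def test_score_invariant_under_peak_permutation(self, pro_pic, rng):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        frags = theoretical_fragments(form, (1, 2))
        s = synthesize_spectrum(form, 2, SyntheticParams(), rng)
        perm = rng.permutation(len(s.mz))
        o = np.argsort(s.mz[perm])
        s2 = Spectrum("p", s.precursor_mz, 2, s.mz[perm][o], s.intensity[perm][o])
        assert score_match(s, frags)[0] == score_match(s2, frags)[0]


@pytest.fixture(scope="module")
def clean_unmodified():
    return generate_dataset(
        n_spectra=200, seed=31, modified_fraction=0.0, artifact_rate=0.0,
        tryptic_fraction=0.0, params=CLEAN,
    )


@pytest.fixture(scope="module")
def base_candidates(clean_unmodified):
    ds = clean_unmodified
    return build_candidates(ds.database, ds.registry, ds.protocol)


class TestClosedSearch:
    def test_recovers_kme3_peptide(self, registry, pro_pic, h3_tail_peptide, rng, histones):
        truth = apply_protocol(h3_tail_peptide, pro_pic, {1: registry["trimethyl"]})
        s = synthesize_spectrum(truth, 2, SyntheticParams(), rng)
        cands = build_candidates(histones, registry, pro_pic) + [truth]
        (psm,) = closed_search([s], cands)
        assert psm.peptide == "KSTGGKAPR"
        assert psm.delta_mass == 0.0
        assert ("trimethyl" in psm.form.assigned_mods_str()
                or (1, "trimethyl") in psm.form.mod_names())

    def test_empty_candidate_set_yields_no_psms(self, clean_unmodified):
        assert closed_search(clean_unmodified.spectra[:5], []) == []

    def test_top1_recovery_at_zero_noise(self, clean_unmodified, base_candidates):
        ds = clean_unmodified
        psms = closed_search(ds.spectra, base_candidates)
        assert len(psms) >= 0.99 * len(ds.spectra)
        correct = sum(
            1 for p in psms
            if p.peptide == next(
                s for s in ds.spectra if s.id == p.spectrum_id
            ).provenance["peptide"]
        )
        assert correct >= 0.99 * len(psms)


class TestOpenSearch:
    def test_lactyl_reported_as_oxidation_delta_at_k14(
        self, registry, pro_pic, h3_tail_peptide, rng, histones
    ):
        """A K14-lactylated peptide searched against candidates carrying
        only the derivatization chemistry shows a +15.99 delta localized
        at K14 (peptide position 6), because lactyl displaces propionyl."""
        truth = apply_protocol(
            h3_tail_peptide, pro_pic, {1: registry["trimethyl"], 6: registry["lactyl"]}
        )
        s = synthesize_spectrum(truth, 2, SyntheticParams(), rng)
        cands = build_candidates(histones, registry, pro_pic) + [
            apply_protocol(h3_tail_peptide, pro_pic, {1: registry["trimethyl"]})
        ]
        (psm,) = open_search([s], cands)
        assert psm.peptide == "KSTGGKAPR"
        assert psm.delta_mass == pytest.approx(15.9949, abs=0.01)
        assert psm.localized and 6 in psm.best_positions

    def test_window_zero_equals_closed(self, clean_unmodified, base_candidates):
        ds = clean_unmodified
        closed = closed_search(
            ds.spectra, base_candidates, SearchConfig(mode="closed", isotope_errors=(0,))
        )
        openz = open_search(
            ds.spectra, base_candidates,
            SearchConfig(mode="open", open_window=(0.0, 0.0), isotope_errors=(0,)),
        )
        assert psm_fingerprint(closed) == psm_fingerprint(openz)

    def test_localization_accuracy_on_spiked_set(self, registry):
        ds = generate_dataset(
            n_spectra=150, seed=41, modified_fraction=1.0, artifact_rate=0.0,
            tryptic_fraction=0.0, params=CLEAN,
        )
        cands = build_candidates(ds.database, ds.registry, ds.protocol)
        psms = open_search(ds.spectra, cands)
        by_id = {s.id: s for s in ds.spectra}
        single = [
            p for p in psms
            if abs(p.delta_mass) > 0.01
            and sum(
                1 for pos, nm in by_id[p.spectrum_id].provenance["mod_names"]
                if ds.registry[nm].category == "biological"
            ) == 1
        ]
        assert len(single) >= 50
        good = 0
        for p in single:
            s = by_id[p.spectrum_id]
            true_pos = [
                pos for pos, nm in s.provenance["mod_names"]
                if ds.registry[nm].category == "biological"
            ]
            if p.peptide == s.provenance["peptide"] and p.localized and set(
                true_pos
            ) & set(p.best_positions):
                good += 1
        # full fragment coverage at zero noise: localization essentially
        # always has a discriminating ion pair
        assert good / len(single) >= 0.9


class TestDmoSearch:
    def test_malonyl_on_h4k77(self, registry, pro_pic, h4_68_78_peptide, rng, histones):
        truth = apply_protocol(h4_68_78_peptide, pro_pic, {10: registry["malonyl"]})
        s = synthesize_spectrum(truth, 2, SyntheticParams(), rng)
        cands = build_candidates(histones, registry, pro_pic)
        (psm,) = dmo_search([s], cands, offsets=[registry["malonyl"]])
        assert psm.offset_name == "malonyl"
        # peptide position 10 -> mature H4 position 77
        assert h4_68_78_peptide.start + psm.offset_position - 1 == 77
        assert psm.n_best_positions == 1

    def test_zero_offsets_equals_closed(self, clean_unmodified, base_candidates):
        ds = clean_unmodified
        cfg_c = SearchConfig(mode="closed", precursor_tol_ppm=10.0, isotope_errors=(0,))
        cfg_d = SearchConfig(mode="dmo", precursor_tol_ppm=10.0, isotope_errors=(0,))
        closed = closed_search(ds.spectra, base_candidates, cfg_c)
        dmo = dmo_search(ds.spectra, base_candidates, cfg_d, offsets=())
        assert psm_fingerprint(closed) == psm_fingerprint(dmo)

    def test_per_offset_recovery_tracks_detection_probability(self, registry):
        ds = generate_dataset(
            n_spectra=200, seed=51, modified_fraction=1.0, artifact_rate=0.0,
            tryptic_fraction=0.0,
            bio_mod_names=("acetyl", "trimethyl", "crotonyl", "glutaryl"),
            params=SyntheticParams(detection_prob=0.9),
        )
        cands = build_candidates(ds.database, ds.registry, ds.protocol)
        offsets = [ds.registry[n] for n in ("acetyl", "trimethyl", "crotonyl", "glutaryl")]
        psms = dmo_search(ds.spectra, cands, offsets=offsets)
        by_id = {s.id: s for s in ds.spectra}
        n_mod_spectra = sum(
            1 for s in ds.spectra
            if any(ds.registry[nm].category == "biological"
                   for _, nm in s.provenance["mod_names"])
        )
        correct = 0
        for p in psms:
            truth = by_id[p.spectrum_id].provenance
            if p.offset_name and (p.offset_position, p.offset_name) in truth["mod_names"]:
                correct += 1
        assert correct >= 0.8 * n_mod_spectra

    def test_all_modes_agree_with_bruteforce_oracle(self, registry, pro_pic, histones, rng):
        """Independent oracle: score every candidate against every
        spectrum with the public scorer, apply the same mass window and
        tie-breaks by exhaustive enumeration."""
        ds = generate_dataset(
            n_spectra=30, seed=61, modified_fraction=0.0, artifact_rate=0.0,
            tryptic_fraction=0.0,
        )
        cands = build_candidates(ds.database, ds.registry, ds.protocol)[:50]
        cfg = SearchConfig(mode="closed", isotope_errors=(0,))
        got = closed_search(ds.spectra, cands, cfg)
        expected = {}
        for s in ds.spectra:
            best = None
            for f in cands:
                if abs(s.precursor_neutral_mass - f.neutral_mass) > (
                    s.precursor_neutral_mass * cfg.precursor_tol_ppm * 1e-6
                ):
                    continue
                score, _ = score_match(s, theoretical_fragments(f, cfg.fragment_charges))
                key = (-score, f.n_mods(), f.sequence, f.assigned_mods_str(), f.is_decoy)
                if best is None or key < best[0]:
                    best = (key, f, score)
            if best:
                expected[s.id] = (best[1].sequence, best[2])
        assert {p.spectrum_id: (p.peptide, p.score) for p in got} == expected


class TestDeltaHistogram:
    def test_all_zero_deltas_empty(self):
        psms = [
            PSM("s", None, 2, 1.0, 0.0, delta_mass=0.0) for _ in range(5)
        ]
        assert len(delta_histogram(psms)) == 0

    def test_modal_bin_at_spiked_artifact(self, registry):
        ds = generate_dataset(
            n_spectra=200, seed=71, modified_fraction=0.0, artifact_rate=0.3,
            artifact_names=("propionyl-ST",), tryptic_fraction=0.0,
        )
        cands = build_candidates(ds.database, ds.registry, ds.protocol)
        psms = open_search(ds.spectra, cands)
        hist = delta_histogram(psms, bin_width=0.01, registry=ds.registry)
        assert len(hist) > 0
        top = hist.iloc[0]
        assert top["mean_delta"] == pytest.approx(56.0262, abs=0.01)
        assert top["count"] == pytest.approx(0.3 * 200, abs=20)
        assert any("propionyl" in a for a in top["annotations"])

    def test_bin_annotations_carry_isobaric_alternatives(self, registry):
        psms = [
            PSM("s", None, 2, 1.0, 0.0, delta_mass=15.9949) for _ in range(3)
        ]
        hist = delta_histogram(psms, bin_width=0.01, registry=registry)
        annots = hist.iloc[0]["annotations"]
        assert "oxidation" in annots

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            delta_histogram([], bin_width=0.0)


class TestPsmTable:
    def test_table_columns_and_write(self, clean_unmodified, base_candidates, tmp_path):
        ds = clean_unmodified
        psms = closed_search(ds.spectra[:10], base_candidates)
        df = write_psm_table(psms, tmp_path / "psm.tsv")
        assert "Number Best Positions" in df.columns
        assert (tmp_path / "psm.tsv").exists()
        assert len(df) == len(psms)
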