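"""Grouped target-decoy FDR, quality filters, isobaric adjudication and
entrapment error estimation."""

import numpy as np
import pytest

from openhist.chemistry import BIOLOGICAL
from openhist.pipeline import build_candidates
from openhist.proteolysis import PeptidoForm, apply_protocol
from openhist.search import PSM, SearchConfig, dmo_search
from openhist.spectra import SyntheticParams, generate_dataset, synthesize_spectrum
from openhist.validation import (
    EntrapmentReport,
    adjudicate_isobaric,
    assign_group,
    compute_fdr,
    entrapment_analysis,
    filter_psms,
)

CLEAN = SyntheticParams(detection_prob=1.0, n_noise_peaks=0, mz_jitter_ppm=0.0)


def make_psm(form, score, spectrum_id="s", species=None, **kw):
    return PSM(spectrum_id, form, 2, score, 0.0, spectrum_species=species, **kw)


class TestAssignGroup:
    def test_kme3_peptide_is_biological(self, registry, pro_pic, h3_tail_peptide):
        form = apply_protocol(h3_tail_peptide, pro_pic, {1: registry["trimethyl"]})
        assert assign_group(make_psm(form, 1.0)) == "biological"

    def test_fully_propionylated_is_chemical_only_strict(self, pro_pic):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        psm = make_psm(form, 1.0)
        assert assign_group(psm, "strict3") == "chemical_only"
        # the two-category convention folds chemistry into "unmodified"
        assert assign_group(psm, "folded2") == "unmodified"

    def test_bare_peptide_is_unmodified(self):
        form = PeptidoForm.build("AGGDER")
        assert assign_group(make_psm(form, 1.0)) == "unmodified"

    def test_group_counts_match_bruteforce_recount(self, registry, pro_pic, rng):
        forms = []
        for _ in range(1000):
            seq = "".join(rng.choice(list("AGSTKLR"), size=8))
            bio = {}
            kpos = [i for i, aa in enumerate(seq, 1) if aa == "K"]
            if kpos and rng.random() < 0.5:
                bio[int(rng.choice(kpos))] = registry["acetyl"]
            derivatized = rng.random() < 0.8
            forms.append(apply_protocol(seq, pro_pic, bio, derivatized=derivatized))
        psms = [make_psm(f, 1.0) for f in forms]
        groups = [assign_group(p) for p in psms]
        for p, g in zip(psms, groups):
            cats = {m.category for _, ms in p.form.mods for m in ms}
            if "biological" in cats:
                assert g == "biological"
            elif cats:
                assert g == "chemical_only"
            else:
                assert g == "unmodified"


class TestComputeFdr:
    def test_all_targets_no_decoys_all_q_zero(self, pro_pic):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        psms = [make_psm(form, s) for s in np.linspace(10, 50, 20)]
        result = compute_fdr(psms, grouped=False, fdr=0.01, peptide_level=False)
        assert all(p.q_value == 0.0 for p in psms)
        assert len(result.accepted) == 20

    def test_interleaved_equal_scores_q_near_one(self, pro_pic):
        tgt = apply_protocol("KSTGGKAPR", pro_pic, {})
        dec = PeptidoForm.build("PAKGGTSKR", is_decoy=True)
        psms = []
        for i in range(50):
            psms.append(make_psm(tgt, 10.0))
            psms.append(make_psm(dec, 10.0))
        compute_fdr(psms, grouped=False, fdr=0.01, peptide_level=False)
        assert all(p.q_value >= 0.9 for p in psms)

    def test_qvalues_monotone_in_score_within_group(self, pro_pic, rng):
        tgt = apply_protocol("KSTGGKAPR", pro_pic, {})
        dec = PeptidoForm.build("PAKGGTSKR", is_decoy=True)
        psms = [make_psm(tgt, float(rng.normal(12, 4))) for _ in range(200)]
        psms += [make_psm(dec, float(rng.normal(8, 4))) for _ in range(200)]
        compute_fdr(psms, grouped=False, peptide_level=False)
        ordered = sorted(psms, key=lambda p: -p.score)
        qs = [p.q_value for p in ordered]
        assert qs == sorted(qs)

    def test_realized_fdp_controlled_in_simulation(self, pro_pic):
        """Decoy scores ~ the null, targets a mixture of true (shifted)
        and false (null) matches; realized false proportion among
        accepted stays near the nominal 1% over 20 seeds."""
        tgt_true = apply_protocol("KSTGGKAPR", pro_pic, {})
        tgt_false = apply_protocol("DAVTYTEHAKR", pro_pic, {})
        dec = PeptidoForm.build("PAKGGTSKR", is_decoy=True)
        fdps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            psms = (
                [make_psm(tgt_true, float(r.normal(25, 3))) for _ in range(400)]
                + [make_psm(tgt_false, float(r.normal(10, 3))) for _ in range(200)]
                + [make_psm(dec, float(r.normal(10, 3))) for _ in range(200)]
            )
            res = compute_fdr(psms, grouped=False, fdr=0.01, peptide_level=False)
            n_false = sum(1 for p in res.accepted if p.form is tgt_false)
            fdps.append(n_false / max(len(res.accepted), 1))
        assert np.mean(fdps) <= 0.015

    def test_decoy_only_group_skipped_with_warning(self, caplog):
        dec = PeptidoForm.build("PAKGGTSKR", is_decoy=True)
        psms = [make_psm(dec, 10.0)]
        with caplog.at_level("WARNING"):
            result = compute_fdr(psms, grouped=False)
        assert result.accepted == []
        assert "no target PSMs" in caplog.text


class TestFilterPsms:
    def _psm(self, form, frac_num, frac_den, n_best=1, delta=0.0, localized=True):
        return PSM(
            "s", form, 2, 10.0, 0.0, delta_mass=delta, localized=localized,
            n_best_positions=n_best, matched_b=frac_num, matched_y=0,
            theor_b=frac_den, theor_y=0,
        )

    def test_all_ions_matched_retained(self, pro_pic):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        assert filter_psms([self._psm(form, 8, 8)]) != []

    def test_threshold_zero_is_identity(self, pro_pic):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        psms = [self._psm(form, 1, 8), self._psm(form, 0, 8)]
        assert filter_psms(psms, 0.0, require_unique_localization=False) == psms

    def test_ambiguous_localization_dropped(self, pro_pic):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        keep = self._psm(form, 8, 8, n_best=1, delta=42.0)
        drop = self._psm(form, 8, 8, n_best=2, delta=42.0)
        unloc = self._psm(form, 8, 8, n_best=1, delta=42.0, localized=False)
        assert filter_psms([keep, drop, unloc]) == [keep]

    def test_idempotent(self, pro_pic):
        form = apply_protocol("KSTGGKAPR", pro_pic, {})
        psms = [self._psm(form, k, 8) for k in range(9)]
        once = filter_psms(psms)
        assert filter_psms(once) == once

    def test_recombinant_control_retains_under_two_percent_modified(self, registry):
        """Spectra of an (almost entirely) unmodified protein searched
        with the full biological offset list: after FDR and the filter
        chain, nearly nothing biologically modified survives."""
        ds = generate_dataset(
            n_spectra=250, seed=81, modified_fraction=0.0, artifact_rate=0.0,
            tryptic_fraction=0.0,
        )
        cands = build_candidates(ds.database, ds.registry, ds.protocol)
        offsets = [m for m in ds.registry.by_category(BIOLOGICAL)
                   if m.name != "pyruvoyl"]
        psms = dmo_search(ds.spectra, cands, offsets=offsets)
        res = compute_fdr(psms, grouped=True, fdr=0.01)
        kept = filter_psms(res.accepted)
        n_modified = sum(1 for p in kept if p.fdr_group == "biological")
        assert n_modified / max(len(psms), 1) < 0.02


class TestAdjudication:
    @pytest.fixture()
    def h4_spectra(self, registry, pro_pic, h4_68_78_peptide):
        rng = np.random.default_rng(17)
        malonyl = apply_protocol(h4_68_78_peptide, pro_pic, {10: registry["malonyl"]})
        pair = apply_protocol(h4_68_78_peptide, pro_pic, {}).with_added_mod(
            8, registry["quinone"]
        )
        spectra, truth = [], []
        for i in range(30):
            spectra.append(synthesize_spectrum(malonyl, 2, CLEAN, rng, f"mal.{i}"))
            truth.append("malonyl")
            spectra.append(synthesize_spectrum(pair, 2, CLEAN, rng, f"pair.{i}"))
            truth.append("pair")
        return spectra, dict(zip([s.id for s in spectra], truth))

    def test_isobaric_pair_discarded_malonyl_kept(
        self, registry, pro_pic, histones, h4_spectra
    ):
        spectra, truth = h4_spectra
        cands = build_candidates(histones, registry, pro_pic)
        psms = dmo_search(spectra, cands, offsets=[registry["malonyl"]])
        adj = adjudicate_isobaric(psms, spectra, registry)
        assert len(adj) == len(spectra)
        correct = sum(
            1 for p in adj
            if (truth[p.spectrum_id] == "malonyl") == (p.verdict == "kept")
        )
        assert correct / len(adj) >= 0.95
        # CO2 satellite series always keeps a true malonyl assignment
        assert all(
            p.verdict == "kept" for p in adj if truth[p.spectrum_id] == "malonyl"
        )

    def test_psm_without_isobaric_alternative_kept(
        self, registry, pro_pic, h3_tail_peptide, histones
    ):
        rng = np.random.default_rng(3)
        form = apply_protocol(h3_tail_peptide, pro_pic, {1: registry["hexose"]})
        s = synthesize_spectrum(form, 2, CLEAN, rng, "hex")
        cands = build_candidates(histones, registry, pro_pic)
        psms = dmo_search([s], cands, offsets=[registry["hexose"]])
        adj = adjudicate_isobaric(psms, [s], registry)
        assert adj[0].verdict == "kept"

    def test_unique_decomposition_never_changes_verdict(self, registry, pro_pic, histones, rng):
        """Offsets whose mass admits only the trivial decomposition are
        untouched by adjudication (invariant)."""
        from openhist.chemistry import decompose_delta

        hexose = registry["hexose"]
        assert len(decompose_delta(hexose.mass, registry, 2, 0.001)) == 1
        ds = generate_dataset(
            n_spectra=40, seed=91, modified_fraction=1.0,
            bio_mod_names=("hexose",), artifact_rate=0.0, tryptic_fraction=0.0,
        )
        cands = build_candidates(ds.database, ds.registry, ds.protocol)
        psms = dmo_search(ds.spectra, cands, offsets=[hexose])
        before = [(p.spectrum_id, p.peptide, p.form.assigned_mods_str()) for p in psms]
        adj = adjudicate_isobaric(psms, ds.spectra, ds.registry)
        after = [(p.spectrum_id, p.peptide, p.form.assigned_mods_str()) for p in adj]
        assert before == after
        assert all(p.verdict == "kept" for p in adj if p.offset_name == "hexose")


class TestEntrapment:
    def test_printed_count_arithmetic(self):
        # agreement with the printed error rates at their precision
        report = EntrapmentReport(total_modified=3320, entrapment_modified=42)
        assert report.error_rate_pct == pytest.approx(1.26, abs=0.01)
        control = EntrapmentReport(total_modified=821, entrapment_modified=3)
        assert control.error_rate_pct == pytest.approx(0.37, abs=0.01)

    def test_zero_entrapment_is_zero_percent(self):
        assert EntrapmentReport(100, 0).error_rate_pct == 0.0

    def test_zero_denominator_undefined(self):
        report = EntrapmentReport(0, 0)
        assert report.error_rate_pct is None
        assert "undefined" in report.to_text()

    def test_grouped_fdr_controls_entrapment_error(self):
        """Two-species run: with grouped FDR at 1% essentially no
        entrapment-origin spectrum is accepted as a biologically modified
        histone peptide, and the grouped error never exceeds the global
        one (median over seeds)."""
        grouped_err, global_err = [], []
        for seed in range(3):
            ds = generate_dataset(
                n_spectra=400, seed=100 + seed, entrapment_fraction=0.4,
                entrapment_db_fraction=0.7,
            )
            cands = build_candidates(
                ds.database, ds.registry, ds.protocol, include_tryptic=True
            )
            offsets = [m for m in ds.registry.by_category(BIOLOGICAL)
                       if m.name != "pyruvoyl"]
            psms = dmo_search(ds.spectra, cands, offsets=offsets)
            hist_accs = {p.accession for p in ds.target_proteins}
            for grouped, out in ((True, grouped_err), (False, global_err)):
                res = compute_fdr(list(psms), grouped=grouped, fdr=0.01)
                kept = filter_psms(res.accepted)
                rate = entrapment_analysis(kept, hist_accs).error_rate_pct
                out.append(rate if rate is not None else 0.0)
        assert all(e <= 1.5 for e in grouped_err)
        assert np.median(grouped_err) <= np.median(global_err)
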