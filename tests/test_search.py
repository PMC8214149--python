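"""Signature-pair detection and MS3 scoring/localization."""

import numpy as np
import pytest

from xlmsn.chem import (
    Mod,
    ModifiedPeptide,
    WATER,
    fragment_ions,
    mz,
    neutral_from_mz,
    peptide_mass,
)
from xlmsn.msn_io import MSnSpectrum
from xlmsn.search import (
    Tolerances,
    assign_charges,
    find_signature_pairs,
    localize_site,
    score_psm,
    search_spectra,
)
from xlmsn.seqdb import DigestIndex, DigestParams, ProteinRecord

TOL = Tolerances()


def brute_force_pairs(spectrum, linker, tol=TOL):
    """O(n^2 z^2) oracle: keys of all pairs reconstructing the precursor."""
    M = neutral_from_mz(spectrum.precursor_mz, spectrum.precursor_z)
    charges = range(1, spectrum.precursor_z)
    tol_da = M * tol.pair_ppm * 1e-6
    found = set()
    peaks = spectrum.peaks
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            for zi in charges:
                for zj in charges:
                    if zi + zj != spectrum.precursor_z:
                        continue
                    ni = neutral_from_mz(peaks[i][0], zi)
                    nj = neutral_from_mz(peaks[j][0], zj)
                    if abs(ni + nj - M) <= tol_da:
                        found.add((i, j, "A+S"))
                    if abs(ni + nj - (M - WATER)) <= tol_da:
                        found.add((i, j, "A+T"))
    return found


def _interlink_ms2(linker, z=4, za=2, zb=2, extra=()):
    """Noiseless worked-example MS2: ADEKK x DLGEEHFK."""
    a = peptide_mass(ModifiedPeptide("ADEKK"))
    b = peptide_mass(ModifiedPeptide("DLGEEHFK"))
    M = a + b + linker.bridge_mass
    peaks = [
        (mz(a + linker.alkene.mono_mass, za), 100.0),
        (mz(b + linker.thiol.mono_mass, zb), 80.0),
        (mz(b + linker.sulfenic.mono_mass, zb), 20.0),
    ]
    peaks += list(extra)
    return MSnSpectrum(scan_id=1, ms_level=2, precursor_mz=mz(M, z),
                       precursor_z=z, peaks=peaks)


class TestAssignCharges:
    def test_candidates_below_precursor(self, sdaso_m):
        s = _interlink_ms2(sdaso_m)
        assert assign_charges(s)[0] == [1, 2, 3]

    def test_empty_spectrum(self):
        s = MSnSpectrum(scan_id=1, ms_level=2, precursor_mz=500.0,
                        precursor_z=3, peaks=[])
        assert assign_charges(s) == []


class TestFindSignaturePairs:
    def test_worked_example_single_at_pair(self, sdaso_m):
        s = _interlink_ms2(sdaso_m)
        pairs = find_signature_pairs(s, sdaso_m)
        at = [p for p in pairs if p.pair_type == "A+T"]
        assert len(at) == 1
        got = sorted((round(s.peaks[at[0].idx_a][0], 2),
                      round(s.peaks[at[0].idx_b][0], 2)))
        assert got == [322.67, 537.75]
        a_s = [p for p in pairs if p.pair_type == "A+S"]
        assert len(a_s) == 1  # the minor sulfenic companion

    def test_matches_brute_force_oracle_100_random_spectra(self, sdaso_m):
        rng = np.random.default_rng(13)
        for _ in range(100):
            z = int(rng.integers(3, 6))
            n = int(rng.integers(5, 30))
            M = float(rng.uniform(1500, 4000))
            peaks = sorted(
                (float(rng.uniform(150, 1500)), float(rng.uniform(1, 100)))
                for _ in range(n))
            s = MSnSpectrum(scan_id=1, ms_level=2, precursor_mz=mz(M, z),
                            precursor_z=z, peaks=peaks)
            got = {(p.idx_a, p.idx_b, p.pair_type)
                   for p in find_signature_pairs(s, sdaso_m)}
            assert got == brute_force_pairs(s, sdaso_m)

    def test_random_noise_rarely_pairs(self, sdaso_m):
        # chance pairing at +-20 ppm is rare in pure-noise spectra; the
        # residue is removed downstream because chance pairs never come
        # with two identifiable MS3 constituents
        rng = np.random.default_rng(17)
        n_with_pairs = 0
        for _ in range(1000):
            peaks = sorted(
                (float(rng.uniform(150, 1500)), 1.0) for _ in range(20))
            s = MSnSpectrum(scan_id=1, ms_level=2,
                            precursor_mz=float(rng.uniform(400, 1200)),
                            precursor_z=3, peaks=peaks)
            if find_signature_pairs(s, sdaso_m):
                n_with_pairs += 1
        assert n_with_pairs <= 50  # <= 5% chance-pair spectra

    def test_dsso_doublet_corroboration(self, dsso):
        lk = dsso
        a = peptide_mass(ModifiedPeptide("AAAKGGR"))
        b = peptide_mass(ModifiedPeptide("LVNELTEFAK"))
        M = a + b + lk.bridge_mass
        peaks = sorted([
            (mz(a + lk.alkene.mono_mass, 2), 100.0),
            (mz(a + lk.thiol.mono_mass, 2), 90.0),   # doublet partner
            (mz(b + lk.sulfenic.mono_mass, 2), 25.0),
            (mz(b + lk.thiol.mono_mass, 2), 90.0),
        ])
        s = MSnSpectrum(scan_id=1, ms_level=2, precursor_mz=mz(M, 4),
                        precursor_z=4, peaks=peaks)
        pairs = find_signature_pairs(s, lk)
        assert pairs and all(p.doublet_corroborated for p in pairs
                             if p.pair_type == "A+S")


class TestScorePsm:
    def _spectrum_for(self, peptide, noise_rng=None, n_noise=0):
        ions = fragment_ions(
            peptide, ("b", "y"),
            neutral_loss=any(m.name == "sulfenic" for m in peptide.mods))
        peaks = [(mz(m, 1), 50.0) for _, m in ions]
        if noise_rng is not None:
            top = max(p[0] for p in peaks)
            peaks += [(float(noise_rng.uniform(100, top * 1.05)), 5.0)
                      for _ in range(n_noise)]
        return MSnSpectrum(scan_id=2, ms_level=3,
                           precursor_mz=mz(peptide.mass, 2), precursor_z=2,
                           peaks=sorted(peaks), parent_scan=1)

    def test_self_match_is_complete(self):
        p = ModifiedPeptide("DLGEEHFK", mods=(Mod(5, "thiol", 100.034672),))
        psm = score_psm(self._spectrum_for(p), p)
        assert psm.matched == psm.n_theoretical
        assert psm.score > 5

    def test_true_peptide_outscores_shuffled_decoy(self):
        rng = np.random.default_rng(23)
        wins = 0
        n_trials = 500
        for _ in range(n_trials):
            n = int(rng.integers(6, 15))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n))
            p = ModifiedPeptide(seq)
            spec = self._spectrum_for(p, noise_rng=rng, n_noise=10)
            letters = list(seq)
            rng.shuffle(letters)
            decoy_seq = "".join(letters)
            if decoy_seq == seq:
                wins += 1  # degenerate shuffle cannot lose
                continue
            true_score = score_psm(spec, p).score
            decoy_score = score_psm(spec, ModifiedPeptide(decoy_seq)).score
            if true_score > decoy_score:
                wins += 1
        assert wins / n_trials >= 0.99

    def test_score_monotone_in_matched_peaks(self):
        p = ModifiedPeptide("DLGEEHFKR")
        full = self._spectrum_for(p)
        scores = []
        for keep in range(len(full.peaks), 0, -2):
            sub = MSnSpectrum(scan_id=2, ms_level=3,
                              precursor_mz=full.precursor_mz, precursor_z=2,
                              peaks=full.peaks[:keep], parent_scan=1)
            scores.append((score_psm(sub, p).matched, score_psm(sub, p).score))
        ordered = sorted(scores)
        assert all(s1 <= s2 + 1e-9 for (_, s1), (_, s2)
                   in zip(ordered, ordered[1:]))


class TestLocalize:
    def test_site_determining_fragments_give_single_site(self):
        # sites far apart in a peptide produce distinct fragment sets
        p_true = ModifiedPeptide("DLGEEHFK", mods=(Mod(2, "thiol", 100.034672),))
        spec = TestScorePsm()._spectrum_for(p_true)
        psms = [score_psm(spec, ModifiedPeptide(
            "DLGEEHFK", mods=(Mod(i, "thiol", 100.034672),)))
            for i in range(1, 9)]
        best = localize_site(psms)
        assert best.ambiguity == (2,)

    def test_terminal_isomers_tie_when_site_ions_absent(self):
        # without the site-determining b8/y1 ions, the two C-terminal
        # glycine placements produce identical matchable ladders
        p_true = ModifiedPeptide("DLGEEHFGG", mods=(Mod(9, "thiol", 100.034672),))
        ions = [(lbl, m) for lbl, m in fragment_ions(p_true)
                if lbl not in ("b8", "y1")]
        spec = MSnSpectrum(
            scan_id=2, ms_level=3, precursor_mz=mz(p_true.mass, 2),
            precursor_z=2, peaks=sorted((mz(m, 1), 50.0) for _, m in ions),
            parent_scan=1)
        psms = [score_psm(spec, ModifiedPeptide(
            "DLGEEHFGG", mods=(Mod(i, "thiol", 100.034672),)))
            for i in (8, 9)]
        best = localize_site(psms)
        assert set(best.ambiguity) == {8, 9}

    def test_below_floor_unidentified(self):
        p = ModifiedPeptide("DLGEEHFK")
        empty = MSnSpectrum(scan_id=2, ms_level=3, precursor_mz=mz(p.mass, 2),
                            precursor_z=2, peaks=[(200.0, 1.0)], parent_scan=1)
        assert localize_site([score_psm(empty, p)]) is None

    def test_requires_psms(self):
        with pytest.raises(ValueError):
            localize_site([])


class TestSearchSpectra:
    def test_noiseless_end_to_end_psms(self, noiseless_sim, small_db, sdaso_m):
        from xlmsn.seqdb import make_decoys

        cfg, truth, spectra = noiseless_sim
        db = make_decoys(small_db, seed=99)
        index = DigestIndex(db, DigestParams())
        result = search_spectra(spectra, index, sdaso_m)
        # every interlink MS2 yields at least one A+T pair
        interlink_scans = [t.ms2_scan for t in truth if t.kind == "interlink"]
        for sid in interlink_scans:
            assert any(p.pair_type == "A+T" for p in result.pairs[sid])
        # and most MS3 spectra identify their generating peptide
        assert len(result.psms) >= 0.9 * sum(
            1 for s in spectra if s.ms_level == 3)

    def test_broken_lineage_rejected(self, sdaso_m, small_db):
        index = DigestIndex(small_db, DigestParams())
        orphan = MSnSpectrum(scan_id=5, ms_level=3, precursor_mz=500.0,
                             precursor_z=2, peaks=[(200.0, 1.0)],
                             parent_scan=999)
        with pytest.raises(ValueError, match="missing MS2 parent"):
            search_spectra([orphan], index, sdaso_m)
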