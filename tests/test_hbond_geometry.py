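"""Geometric hydrogen-bond detection, typing and the N1/N3 census."""

import numpy as np
import pytest

from microhydrate.hbond_geometry import (
    ContactCriteria, census_summary, detect_contacts, out_of_plane_angle,
)
from microhydrate.io_structures import (
    Structure, label_imidazole, perceive_fragments,
)
from microhydrate import synthetic_data as sd

from conftest import place_water_donating_to, random_rotation


class TestDetection:
    def test_linear_water_dimer_single_ohO(self, water_dimer):
        rep = detect_contacts(water_dimer)
        kinds = [c.kind for c in rep.contacts]
        assert kinds == ["OH...O"]
        c = rep.contacts[0]
        assert c.angle_DHA == pytest.approx(180.0, abs=1.0)
        assert c.d_HA == pytest.approx(2.9 - 0.9572, abs=1e-6)

    def test_water_donating_to_n3(self, water_on_n3):
        frags = perceive_fragments(water_on_n3)
        roles = label_imidazole(water_on_n3, frags)
        rep = detect_contacts(water_on_n3, roles, frags)
        assert rep.census["N3_accepted"] == 1
        assert [c.kind for c in rep.contacts
                if c.kind == "OH...N3"] == ["OH...N3"]

    def test_imzw3_motif_census(self, imidazole):
        # three-water bridge: one water accepts from N1–H, one donates to
        # N3, a third bridges them — census must read one donated (N1H)
        # and one accepted (N3) hydrogen bond, as in the trihydrate motif
        roles0 = label_imidazole(imidazole)
        n3 = imidazole.coords[roles0.N3]
        h_n1 = imidazole.coords[roles0.H_N1]
        n1 = imidazole.coords[roles0.N1]
        normal = roles0.ring_plane_normal
        # water 1 accepts from N1–H, in plane
        d1 = (h_n1 - n1) / np.linalg.norm(h_n1 - n1)
        o1 = h_n1 + d1 * 1.9
        w1 = np.array([o1, o1 + [0.76, 0.59, 0.0], o1 + [-0.76, 0.59, 0.0]])
        # water 2 donates to N3 from out of plane
        approach = (n3 / np.linalg.norm(n3)) * 0.5 + normal * 0.866
        approach /= np.linalg.norm(approach)
        w2, _ = place_water_donating_to(n3, approach, 1.9)
        # water 3 far on the other side (spectator)
        w3 = sd.WATER_COORDS + (-n3 / np.linalg.norm(n3)) * 8.0
        s = Structure(imidazole.elements + ["O", "H", "H"] * 3,
                      np.vstack([imidazole.coords, w1, w2, w3]),
                      label="IMZW3_motif")
        frags = perceive_fragments(s)
        assert frags.n_fragments == 4
        roles = label_imidazole(s, frags)
        rep = detect_contacts(s, roles, frags)
        # oracle: manual enumeration of the two implanted triples
        assert rep.census["N1H_donated"] == 1
        assert rep.census["N3_accepted"] == 1
        assert rep.out_of_plane[list(rep.out_of_plane)[0]] == pytest.approx(
            60.0, abs=5.0)

    def test_no_intra_fragment_contacts(self, study_small):
        for members in study_small.gas_ensembles.values():
            s = members[0][0]
            frags = perceive_fragments(s)
            roles = label_imidazole(s, frags)
            rep = detect_contacts(s, roles, frags)
            for c in rep.contacts:
                if c.acceptor is not None:
                    assert frags.fragment_ids[c.donor] != \
                        frags.fragment_ids[c.acceptor]

    def test_rigid_motion_and_reorder_invariance(self, water_on_n3):
        frags = perceive_fragments(water_on_n3)
        roles = label_imidazole(water_on_n3, frags)
        ref = detect_contacts(water_on_n3, roles, frags)
        rng = np.random.default_rng(12)
        rot = random_rotation(rng)
        s2 = Structure(list(water_on_n3.elements),
                       water_on_n3.coords @ rot.T + [5.0, -3.0, 1.0])
        rep2 = detect_contacts(s2, label_imidazole(s2))
        assert rep2.census == ref.census
        assert len(rep2.contacts) == len(ref.contacts)

    def test_tightening_cutoffs_monotone(self, study_small):
        s = study_small.gas_ensembles[3][0][0]
        frags = perceive_fragments(s)
        roles = label_imidazole(s, frags)
        counts = []
        for d_ha in (3.0, 2.6, 2.2, 1.8):
            crit = ContactCriteria(d_HA_max=d_ha, d_Hpi_max=d_ha + 0.4)
            counts.append(detect_contacts(s, roles, frags, crit).n_contacts)
        assert counts == sorted(counts, reverse=True)
        counts = []
        for ang in (100.0, 120.0, 150.0, 175.0):
            crit = ContactCriteria(angle_DHA_min=ang)
            counts.append(detect_contacts(s, roles, frags, crit).n_contacts)
        assert counts == sorted(counts, reverse=True)


class TestOutOfPlane:
    def test_in_plane_zero(self, imidazole):
        roles = label_imidazole(imidazole)
        n3 = imidazole.coords[roles.N3]
        o = n3 + (n3 / np.linalg.norm(n3)) * 3.0    # radially out, in plane
        assert out_of_plane_angle(roles, o, coords_N3=n3) == pytest.approx(
            0.0, abs=1e-6)

    def test_along_normal_ninety(self, imidazole):
        roles = label_imidazole(imidazole)
        n3 = imidazole.coords[roles.N3]
        o = n3 + roles.ring_plane_normal * 3.0
        assert out_of_plane_angle(roles, o, coords_N3=n3) == pytest.approx(
            90.0, abs=1e-6)

    def test_rotation_invariance(self, imidazole):
        roles = label_imidazole(imidazole)
        n3 = imidazole.coords[roles.N3]
        o = n3 + (roles.ring_plane_normal * 0.5
                  + np.array([0.6, 0.2, 0.0])) * 3.0
        a = out_of_plane_angle(roles, o, coords_N3=n3)
        rng = np.random.default_rng(2)
        rot = random_rotation(rng)
        s2 = Structure(list(imidazole.elements), imidazole.coords @ rot.T)
        roles2 = label_imidazole(s2)
        a2 = out_of_plane_angle(roles2, rot @ o,
                                coords_N3=s2.coords[roles2.N3])
        assert a2 == pytest.approx(a, abs=1e-6)


class TestCensus:
    def test_single_report_is_itself(self, water_on_n3):
        rep = detect_contacts(water_on_n3, label_imidazole(water_on_n3))
        summ = census_summary([rep])
        assert summ["N3_accepted"]["modal"] == 1

    def test_all_empty_reports(self, water):
        far = Structure(water.elements * 2,
                        np.vstack([water.coords, water.coords + [12, 0, 0]]))
        reports = [detect_contacts(far) for _ in range(3)]
        assert all(r.n_contacts == 0 for r in reports)
        assert census_summary(reports) == {}

    def test_large_cap_modal_counts(self, imidazole):
        # deterministic 64-water cap saturating both ring faces: one water
        # donates into N3, one accepts from N1H, the rest shell the solute
        roles = label_imidazole(imidazole)
        n3 = imidazole.coords[roles.N3]
        h_n1 = imidazole.coords[roles.H_N1]
        n1 = imidazole.coords[roles.N1]
        normal = roles.ring_plane_normal
        blocks, els = [], []
        approach = (n3 / np.linalg.norm(n3)) * 0.5 + normal * 0.866
        approach /= np.linalg.norm(approach)
        w, e = place_water_donating_to(n3, approach, 1.9)
        blocks.append(w), els.extend(e)
        d1 = (h_n1 - n1) / np.linalg.norm(h_n1 - n1)
        o1 = h_n1 + d1 * 1.9
        blocks.append(np.array([o1, o1 + [0.76, 0.59, 0.0],
                                o1 + [-0.76, 0.59, 0.0]]))
        els.extend(["O", "H", "H"])
        # 62 shell waters on a Fibonacci sphere, radius 7 Å
        golden = np.pi * (3 - np.sqrt(5))
        for k in range(62):
            z = 1 - 2 * (k + 0.5) / 62
            r = np.sqrt(1 - z * z)
            th = golden * k
            center = 7.0 * np.array([r * np.cos(th), r * np.sin(th), z])
            blocks.append(sd.WATER_COORDS + center)
            els.extend(["O", "H", "H"])
        s = Structure(imidazole.elements + els,
                      np.vstack([imidazole.coords] + blocks), label="cap64")
        frags = perceive_fragments(s)
        assert frags.fragment_formulas.count("H2O") == 64
        rep = detect_contacts(s, label_imidazole(s, frags), frags)
        summ = census_summary([rep])
        assert summ["N3_accepted"]["modal"] >= 1
        assert summ["N1H_donated"]["modal"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            census_summary([])
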