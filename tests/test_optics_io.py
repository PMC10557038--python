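import struct
from pathlib import Path

import numpy as np
import pytest

from headmc.history import (PhotonHistory, read_mch, read_photon_history,
                            write_mch, write_photon_history)
from headmc.optics import (SimulationConfig, TissueOptics,
                           read_optical_properties_dat, read_session_json,
                           write_optical_properties_dat, write_session_json)
from headmc.placement import IntersectionCurve, Optode, OptodeLayout

DATA = Path(__file__).parent / "data"


def make_layout():
    curve = IntersectionCurve(
        np.array([[0., 0, 70], [5, 0, 69.5], [10, 0, 68.5]]), closed=False)
    dets = [Optode(pos=[5., 0, 69.5], direction=[0., 0, -1], radius_mm=0.7,
                   requested_mm=5.0, achieved_mm=5.01),
            Optode(pos=[10., 0, 68.5], direction=[0., 0, -1], radius_mm=0.7,
                   requested_mm=50.0, achieved_mm=49.97)]
    return OptodeLayout(source_pos=[0., 0, 70], source_dir=[0., 0, -1],
                        detectors=dets, poi=[5., 0, 69.5], curve=curve)


def make_config(**kw):
    defaults = dict(photon_count=12345, layout=make_layout(),
                    optics=TissueOptics.typical_head(), mesh_ref="head.msh",
                    seed=7, wavelength_nm=785.0, session_name="golden")
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSessionJson:
    def test_roundtrip_bit_exact(self, tmp_path):
        cfg = make_config()
        p = tmp_path / "session.json"
        write_session_json(cfg, p)
        back = read_session_json(p)
        assert back.photon_count == cfg.photon_count
        assert back.seed == cfg.seed
        assert back.time_gates == cfg.time_gates
        assert back.wavelength_nm == cfg.wavelength_nm
        np.testing.assert_array_equal(back.layout.source_pos,
                                      cfg.layout.source_pos)
        for a, b in zip(back.layout.detectors, cfg.layout.detectors):
            np.testing.assert_array_equal(a.pos, b.pos)
            assert a.radius_mm == b.radius_mm
            assert a.achieved_mm == b.achieved_mm
        for f in ("mua", "mus", "g", "n", "alpha_Db"):
            np.testing.assert_array_equal(getattr(back.optics, f),
                                          getattr(cfg.optics, f))

    def test_detector_array_structure(self, tmp_path):
        import json

        p = tmp_path / "session.json"
        write_session_json(make_config(), p)
        doc = json.loads(p.read_text())
        dets = doc["Optode"]["Detector"]
        assert len(dets) == 2
        assert all(d["R"] == 0.7 for d in dets)

    def test_matches_golden_file(self, tmp_path):
        p = tmp_path / "session.json"
        write_session_json(make_config(), p)
        assert p.read_text() == (DATA / "golden_session.json").read_text()

    def test_invalid_wavelength_rejected(self):
        with pytest.raises(ValueError, match="wavelength"):
            make_config(wavelength_nm=500.0)

    def test_invalid_gates_rejected(self):
        with pytest.raises(ValueError, match="gate"):
            make_config(time_gates=(1e-9, 1e-10, 1e-10))


class TestPropertiesDat:
    def test_five_data_lines(self, tmp_path):
        p = tmp_path / "props.dat"
        write_optical_properties_dat(TissueOptics.typical_head(), p)
        lines = [l for l in p.read_text().splitlines() if l.strip()]
        assert len(lines) == 1 + 5  # header + one line per tissue

    def test_roundtrip_to_1e6(self, tmp_path):
        optics = TissueOptics.typical_head()
        p = tmp_path / "props.dat"
        write_optical_properties_dat(optics, p)
        back = read_optical_properties_dat(p)
        for f in ("mua", "mus", "g", "n"):
            np.testing.assert_allclose(getattr(back, f), getattr(optics, f),
                                       atol=1e-6)

    def test_matches_golden_file_bytewise(self, tmp_path):
        p = tmp_path / "props.dat"
        write_optical_properties_dat(TissueOptics.typical_head(), p)
        assert p.read_bytes() == (DATA / "golden_props.dat").read_bytes()

    def test_writer_deterministic(self, tmp_path):
        a, b = tmp_path / "a.dat", tmp_path / "b.dat"
        write_optical_properties_dat(TissueOptics.typical_head(), a)
        write_optical_properties_dat(TissueOptics.typical_head(), b)
        assert a.read_bytes() == b.read_bytes()


class TestTissueOptics:
    def test_musp_definition(self):
        o = TissueOptics(mua=[0.01] * 5, mus=[10.0] * 5, g=[0.9] * 5,
                         n=[1.37] * 5)
        np.testing.assert_allclose(o.musp, 1.0)

    @pytest.mark.parametrize("field,value", [
        ("mua", [-0.1] * 5), ("mus", [0.0] * 5), ("g", [1.5] * 5),
        ("n", [0.9] * 5), ("alpha_Db", [-1e-6] * 5)])
    def test_validation(self, field, value):
        kw = dict(mua=[0.01] * 5, mus=[1.0] * 5, g=[0.0] * 5, n=[1.37] * 5,
                  alpha_Db=[0.0] * 5)
        kw[field] = value
        with pytest.raises(ValueError):
            TissueOptics(**kw)


def make_history(r=3, seed=0):
    rng = np.random.default_rng(seed)
    return PhotonHistory(
        det_id=rng.integers(1, 3, size=r),
        ppath=rng.uniform(0, 50, size=(r, 5)),
        mom=rng.uniform(0, 100, size=(r, 5)),
        weight=rng.uniform(0.1, 1.0, size=r))


class TestInternalHistory:
    def test_roundtrip_exact(self, tmp_path):
        h = make_history(1000)
        p = tmp_path / "hist.h5"
        write_photon_history(h, p)
        back = read_photon_history(p, dialect="internal")
        np.testing.assert_array_equal(back.det_id, h.det_id)
        np.testing.assert_array_equal(back.ppath, h.ppath)
        np.testing.assert_array_equal(back.mom, h.mom)
        np.testing.assert_array_equal(back.weight, h.weight)
        assert back.unit_mm == h.unit_mm

    def test_empty_history_roundtrip(self, tmp_path):
        h = PhotonHistory(det_id=np.empty(0, int), ppath=np.empty((0, 5)),
                          mom=np.empty((0, 5)), weight=np.empty(0))
        p = tmp_path / "empty.h5"
        write_photon_history(h, p)
        assert len(read_photon_history(p)) == 0

    def test_large_roundtrip_exact_floats(self, tmp_path):
        h = make_history(100_000, seed=3)
        p = tmp_path / "big.h5"
        write_photon_history(h, p)
        back = read_photon_history(p)
        np.testing.assert_array_equal(back.ppath, h.ppath)

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_photon_history(tmp_path / "x", dialect="csv")


class TestMchDialect:
    def test_hand_constructed_fixture_decodes(self, tmp_path):
        """Byte-by-byte fixture: 3 records, 5 media, unitmm = 0.5."""
        media, cols, unitmm = 5, 12, 0.5
        rows = np.arange(3 * cols, dtype="<f4").reshape(3, cols)
        rows[:, 0] = [1, 2, 1]                    # detector ids
        rows[:, -1] = [0.5, 0.25, 1.0]            # weights
        header = struct.pack("<4s7I f I f i I I 2i", b"MCXH", 1, media, 2,
                             cols, 1000, 3, 3, unitmm, 0, 1.0, 1, 1, 0, 0, 0)
        p = tmp_path / "fix.mch"
        p.write_bytes(header + rows.tobytes())
        h = read_mch(p)
        assert len(h) == 3
        assert h.ppath.shape == (3, 5)
        np.testing.assert_array_equal(h.det_id, [1, 2, 1])
        # pathlengths are scaled by unitmm to mm
        np.testing.assert_allclose(h.ppath[0], rows[0, 1:6] * unitmm)
        np.testing.assert_allclose(h.mom[1], rows[1, 6:11])
        np.testing.assert_allclose(h.weight, [0.5, 0.25, 1.0])

    def test_write_read_roundtrip(self, tmp_path):
        h = make_history(50)
        p = tmp_path / "h.mch"
        write_mch(h, p)
        back = read_mch(p)
        np.testing.assert_array_equal(back.det_id, h.det_id)
        np.testing.assert_allclose(back.ppath, h.ppath, rtol=1e-6)
        np.testing.assert_allclose(back.weight, h.weight, rtol=1e-6)

    def test_weight_reconstructed_from_optics(self, tmp_path):
        h = make_history(20)
        optics = TissueOptics.typical_head()
        h = PhotonHistory(h.det_id, h.ppath, h.mom,
                          np.exp(-(h.ppath * optics.mua).sum(axis=1)))
        p = tmp_path / "h.mch"
        write_mch(h, p, include_weight=False)
        back = read_mch(p, optics=optics)
        np.testing.assert_allclose(back.weight, h.weight, rtol=1e-5)

    def test_bad_magic_rejected(self, tmp_path):
        p = tmp_path / "bad.mch"
        p.write_bytes(b"NOPE" + b"\0" * 100)
        with pytest.raises(ValueError, match="magic"):
            read_mch(p)

    def test_inconsistent_columns_rejected(self, tmp_path):
        header = struct.pack("<4s7I f I f i I I 2i", b"MCXH", 1, 5, 1,
                             7, 10, 0, 0, 1.0, 0, 1.0, 1, 1, 0, 0, 0)
        p = tmp_path / "bad.mch"
        p.write_bytes(header)
        with pytest.raises(ValueError, match="column count"):
            read_mch(p)

    def test_empty_record_file(self, tmp_path):
        h = PhotonHistory(det_id=np.empty(0, int), ppath=np.empty((0, 5)),
                          mom=np.empty((0, 5)), weight=np.empty(0))
        p = tmp_path / "empty.mch"
        write_mch(h, p)
        assert len(read_mch(p)) == 0
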