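import gzip

import numpy as np
import pytest

from isopair.mz_io import FormatError, extract_xic, read_run
from isopair.simulate import SimConfig, generate_run, random_metabolites, write_run

from .conftest import gaussian_run

MZXML_TWO_SCANS = """<?xml version="1.0" encoding="ISO-8859-1"?>
<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
 <msRun scanCount="3">
  <scan num="1" msLevel="1" centroided="1" retentionTime="PT1.5S" peaksCount="2">
   <peaks precision="32" byteOrder="network" pairOrder="m/z-int">{p1}</peaks>
  </scan>
  <scan num="2" msLevel="2" centroided="1" retentionTime="PT2.0S" peaksCount="1">
   <peaks precision="32" byteOrder="network" pairOrder="m/z-int">{p2}</peaks>
  </scan>
  <scan num="3" msLevel="1" centroided="1" retentionTime="PT2.5S" peaksCount="1">
   <peaks precision="32" byteOrder="network" pairOrder="m/z-int">{p2}</peaks>
  </scan>
 </msRun>
</mzXML>
"""


def _mzxml_peaks(pairs):
    import base64
    import struct

    flat = [v for p in pairs for v in p]
    return base64.b64encode(struct.pack(f">{len(flat)}f", *flat)).decode()


@pytest.fixture(scope="module")
def sim_run_and_file(tmp_path_factory):
    sim = SimConfig(n_scans=40, noise_peaks_per_scan=5, seed=3)
    specs = random_metabolites(2, seed=3, config=sim, min_separation_scans=1.0)
    run, _ = generate_run(specs, sim, "io")
    path = tmp_path_factory.mktemp("io") / "io.mzML"
    write_run(run, path)
    return run, path


class TestReadRun:
    def test_round_trip_lossless(self, sim_run_and_file):
        run, path = sim_run_and_file
        back = read_run(path)
        assert len(back) == len(run)
        for a, b in zip(run, back):
            assert len(a) == len(b)
            assert b.rt_seconds == pytest.approx(a.rt_seconds, abs=1e-4)
            np.testing.assert_allclose(b.mz, a.mz, atol=1e-6)
            np.testing.assert_allclose(b.intensity, a.intensity, rtol=1e-3)

    def test_gzip_container(self, sim_run_and_file, tmp_path):
        _, path = sim_run_and_file
        gz = tmp_path / "run.mzML.gz"
        gz.write_bytes(gzip.compress(path.read_bytes()))
        assert len(read_run(gz)) == len(read_run(path))

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.mzML"
        p.write_text("")
        with pytest.raises(FormatError):
            read_run(p)

    def test_garbage_is_format_error(self, tmp_path):
        p = tmp_path / "bad.mzML"
        p.write_text("<mzML><spectrum></mzML>")
        with pytest.raises(FormatError):
            read_run(p)

    def test_profile_mode_rejected(self, sim_run_and_file, tmp_path):
        _, path = sim_run_and_file
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        p = tmp_path / "profile.mzML"
        p.write_text(text)
        with pytest.raises(FormatError, match="centroid"):
            read_run(p)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_run("/nonexistent/file.mzML")

    def test_mzxml_ms2_skipped_and_rt_parsed(self, tmp_path):
        text = MZXML_TWO_SCANS.format(
            p1=_mzxml_peaks([(400.5, 1000.0), (500.25, 2000.0)]),
            p2=_mzxml_peaks([(300.125, 512.0)]),
        )
        p = tmp_path / "two.mzXML"
        p.write_text(text)
        run = read_run(p)
        assert len(run) == 2  # the msLevel=2 scan is dropped
        assert run.spectra[0].rt_seconds == pytest.approx(1.5)
        assert run.spectra[0].mz == pytest.approx([400.5, 500.25])
        assert run.spectra[1].intensity == pytest.approx([512.0])

    def test_mzxml_profile_rejected(self, tmp_path):
        text = MZXML_TWO_SCANS.format(
            p1=_mzxml_peaks([(400.5, 1000.0)]), p2=_mzxml_peaks([(300.0, 1.0)])
        ).replace('centroided="1"', 'centroided="0"', 1)
        p = tmp_path / "prof.mzXML"
        p.write_text(text)
        with pytest.raises(FormatError):
            read_run(p)


class TestExtractXic:
    def test_single_peak_single_scan(self):
        run = gaussian_run([], n_scans=5)
        run.spectra[3].mz = np.array([500.0])
        run.spectra[3].intensity = np.array([1e5])
        xic = extract_xic(run, 500.0, 2.5)
        expected = np.zeros(5)
        expected[3] = 1e5
        np.testing.assert_array_equal(xic.intensities, expected)

    def test_target_20ppm_away_is_empty(self):
        run = gaussian_run([], n_scans=5)
        run.spectra[3].mz = np.array([500.0])
        run.spectra[3].intensity = np.array([1e5])
        xic = extract_xic(run, 500.0100, 2.5)
        assert not xic.intensities.any()

    def test_two_peaks_in_window_are_summed(self):
        run = gaussian_run([], n_scans=2)
        run.spectra[0].mz = np.array([500.0000, 500.0006])
        run.spectra[0].intensity = np.array([3e4, 4e4])
        xic = extract_xic(run, 500.0003, 2.5)
        assert xic.intensities[0] == pytest.approx(7e4)

    @pytest.mark.parametrize("ppm_pair", [(1.0, 2.5), (2.5, 10.0), (10.0, 50.0)])
    def test_monotone_in_ppm(self, sim_run_and_file, ppm_pair):
        run, _ = sim_run_and_file
        narrow, wide = ppm_pair
        target = float(run.spectra[10].mz[0]) if len(run.spectra[10]) else 300.0
        a = extract_xic(run, target, narrow).intensities
        b = extract_xic(run, target, wide).intensities
        assert np.all(b >= a)

    def test_invalid_ppm(self, sim_run_and_file):
        run, _ = sim_run_and_file
        with pytest.raises(ValueError):
            extract_xic(run, 500.0, 0.0)
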