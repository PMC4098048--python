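"""Synthetic paired native/U-¹³C LC-HRMS runs with ground truth.

The generator emulates the measurement model underlying the pipeline: each
metabolite elutes as a Gaussian chromatographic peak, ionises into one or
more ESI species ([M+H]⁺, [M+Na]⁺, [M+H−H₂O]⁺, [M+2H]²⁺), and — because
the injected sample is a 1:1 (v/v) mixture of a native and a uniformly
¹³C-labelled metabolome — every ion species contributes two mirror-imaged
binomial isotopologue ladders: the natural one anchored at the
monoisotopic signal M (per-atom ¹³C probability ≈ 1.1 %) and the enriched
one anchored at the fully labelled signal M′ = M + n_C·1.00335/z
(enrichment 97–99.5 %).  Chemical noise is modelled as isolated random
centroid peaks, and matrix effects as one multiplicative log-normal
factor per sample applied to every intensity of the run.

Runs are written as standard mzML so the whole pipeline can be exercised
file-in/file-out; every generated ion is recorded in a ground-truth table
joinable with detection output on (m/z, Rt).
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd

from .isotope_math import (
    DELTA_C,
    DEFAULT_ADDUCTS,
    EnrichmentModel,
    binomial_pattern,
)
from .mz_io import Run, Spectrum

__all__ = [
    "MetaboliteSpec",
    "SimConfig",
    "generate_run",
    "write_run",
    "random_metabolites",
]


@dataclass(frozen=True)
class MetaboliteSpec:
    """Ground-truth description of one simulated metabolite."""

    neutral_mass: float                       # u
    n_c: int                                  # carbon atoms
    rt_seconds: float                         # apex retention time
    peak_sigma_scans: float = 4.0             # chromatographic width
    base_abundance: float = 1e6               # apex summed ion counts
    #: (adduct name, relative intensity); names from the default adduct table.
    ion_species: tuple[tuple[str, float], ...] = (("[M+H]+", 1.0),)
    #: per-sample biological multiplier (missing sample -> 1.0).
    per_sample_factor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_c < 1 or self.base_abundance <= 0 or not self.ion_species:
            raise ValueError("invalid MetaboliteSpec")


@dataclass(frozen=True)
class SimConfig:
    """World parameters of one simulated LC-HRMS acquisition."""

    n_scans: int = 600
    scan_interval_seconds: float = 1.0
    enrichment: EnrichmentModel = field(default_factory=EnrichmentModel)
    noise_peaks_per_scan: int = 50
    noise_intensity_range: tuple[float, float] = (500.0, 30_000.0)
    matrix_effect_sigma: float = 0.0          # sd of the per-sample log-factor
    mode: str = "mixed"                       # mixed | native_only | blank
    seed: int = 0
    mz_jitter_ppm: float = 1.0                # per-peak mass error, < tolerance
    merge_ppm: float = 2.0                    # instrument-resolution merging
    mz_range: tuple[float, float] = (100.0, 1000.0)
    ladder_truncate: float = 1e-4

    def __post_init__(self) -> None:
        if self.mode not in ("mixed", "native_only", "blank"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _species_ladders(
    spec: MetaboliteSpec, config: SimConfig
) -> list[tuple[float, int, float, np.ndarray, np.ndarray, np.ndarray]]:
    """Per ion species: (mz_m, z, rel, offsets, abundances, native mask).

    The native mask marks the natural-abundance ladder, which carries the
    per-sample biological factor; the labelled reference ladder is the
    same pooled material in every sample and is left unscaled.
    """
    out = []
    for adduct, rel in spec.ion_species:
        shift, z = DEFAULT_ADDUCTS[adduct]
        mz_m = (spec.neutral_mass + shift) / z
        ks, abunds, native = [], [], []
        if config.mode != "blank":
            for k, a in binomial_pattern(
                spec.n_c, config.enrichment.p_natural, config.ladder_truncate
            ):
                ks.append(k)
                abunds.append(a)
                native.append(True)
            if config.mode == "mixed":
                for k, a in binomial_pattern(
                    spec.n_c, config.enrichment.p_enriched, config.ladder_truncate
                ):
                    ks.append(k)
                    abunds.append(a)
                    native.append(False)
        offsets = np.array(ks, dtype=float) * DELTA_C / z
        return_native = np.array(native, dtype=bool)
        out.append((mz_m, z, rel, offsets, np.array(abunds), return_native))
    return out


def _merge_close(mz: np.ndarray, inten: np.ndarray, ppm: float):
    """Merge peaks closer than the instrument resolution (ppm), summing
    intensities at the intensity-weighted mean m/z."""
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    out_mz: list[float] = []
    out_in: list[float] = []
    for m, i in zip(mz, inten):
        if out_mz and (m - out_mz[-1]) <= ppm * 1e-6 * m:
            tot = out_in[-1] + i
            out_mz[-1] = (out_mz[-1] * out_in[-1] + m * i) / tot
            out_in[-1] = tot
        else:
            out_mz.append(m)
            out_in.append(i)
    return np.array(out_mz), np.array(out_in)


def generate_run(
    specs: list[MetaboliteSpec], config: SimConfig, sample_id: str = "sample"
) -> tuple[Run, pd.DataFrame]:
    """Simulate one centroid run and its ground-truth ion table.

    Deterministic for a fixed ``(config.seed, sample_id)``; the
    ground-truth table has one row per (metabolite, ion species) with the
    anchor m/z values of M and M′, charge, carbon count and apex Rt.
    Blank mode emits noise only and an empty truth table.
    """
    rng = np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF]
    )
    matrix_factor = (
        float(np.exp(rng.normal(0.0, config.matrix_effect_sigma)))
        if config.matrix_effect_sigma > 0
        else 1.0
    )
    scans = np.arange(config.n_scans)
    per_scan_mz: list[list[np.ndarray]] = [[] for _ in scans]
    per_scan_in: list[list[np.ndarray]] = [[] for _ in scans]
    truth_rows = []

    active = [] if config.mode == "blank" else specs
    for mi, spec in enumerate(active):
        apex = spec.rt_seconds / config.scan_interval_seconds
        bio = spec.per_sample_factor.get(sample_id, 1.0)
        height = spec.base_abundance
        lo = max(0, int(np.floor(apex - 5 * spec.peak_sigma_scans)))
        hi = min(config.n_scans, int(np.ceil(apex + 5 * spec.peak_sigma_scans)) + 1)
        profile = height * np.exp(
            -((scans[lo:hi] - apex) ** 2) / (2 * spec.peak_sigma_scans**2)
        )
        for mz_m, z, rel, offsets, abunds, native in _species_ladders(spec, config):
            ladder_scale = np.where(native, bio, 1.0)
            truth_rows.append(
                {
                    "sample": sample_id,
                    "metabolite": mi,
                    "adduct": "",
                    "mz_m": mz_m,
                    "mz_mprime": mz_m + spec.n_c * DELTA_C / z,
                    "z": z,
                    "n_c": spec.n_c,
                    "rt_seconds": spec.rt_seconds,
                    "apex_scan": apex,
                    "height": height * rel * bio,
                }
            )
            for si, h in zip(range(lo, hi), profile):
                inten = h * rel * abunds * ladder_scale
                mzs = mz_m + offsets
                if config.mz_jitter_ppm > 0:
                    mzs = mzs * (
                        1.0
                        + rng.uniform(-1, 1, mzs.size) * config.mz_jitter_ppm * 1e-6
                    )
                per_scan_mz[si].append(mzs)
                per_scan_in[si].append(inten)
    # record adduct names in acquisition order of ion_species
    r = 0
    for spec in active:
        for adduct, _ in spec.ion_species:
            truth_rows[r]["adduct"] = adduct
            r += 1

    spectra = []
    for si in range(config.n_scans):
        if config.noise_peaks_per_scan > 0:
            nmz = rng.uniform(*config.mz_range, config.noise_peaks_per_scan)
            nin = rng.uniform(
                *config.noise_intensity_range, config.noise_peaks_per_scan
            )
            per_scan_mz[si].append(nmz)
            per_scan_in[si].append(nin)
        if per_scan_mz[si]:
            mz = np.concatenate(per_scan_mz[si])
            inten = np.concatenate(per_scan_in[si]) * matrix_factor
            mz, inten = _merge_close(mz, inten, config.merge_ppm)
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        spectra.append(
            Spectrum(
                scan_index=si,
                rt_seconds=(si + 1) * config.scan_interval_seconds,
                mz=mz,
                intensity=inten,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample", "metabolite", "adduct", "mz_m", "mz_mprime",
            "z", "n_c", "rt_seconds", "apex_scan", "height",
        ],
    )
    run = Run(spectra=spectra, source_path=f"<simulated:{sample_id}>")
    run.metadata["matrix_factor"] = matrix_factor
    run.metadata["sample_id"] = sample_id
    return run, truth


def random_metabolites(
    n: int,
    seed: int = 0,
    config: SimConfig | None = None,
    nc_range: tuple[int, int] = (5, 60),
    n_species_range: tuple[int, int] = (1, 3),
    abundance_range: tuple[float, float] = (1e6, 5e6),
    min_separation_scans: float = 8.0,
) -> list[MetaboliteSpec]:
    """Draw a realistic random metabolite panel.

    Carbon counts are uniform over ``nc_range``; neutral masses follow a
    CH₂O-ish mass-per-carbon (12–21 u/C) subject to the instrument scan
    range; each metabolite carries [M+H]⁺ plus up to two further species
    with relative intensities 0.3–1.  Apices are laid on an evenly spaced
    grid (jittered ±1 scan) so that distinct metabolites stay
    chromatographically separated, as on a real gradient.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    extra_pool = ["[M+Na]+", "[M+H-H2O]+", "[M+2H]2+"]
    margin = min(24.0, max(2.0, 0.15 * config.n_scans))
    usable = config.n_scans - 2 * margin
    if usable < n * min_separation_scans:
        raise ValueError("run too short to separate that many metabolites")
    grid = margin + (np.arange(n) + 0.5) * usable / n
    grid = grid + rng.uniform(-1, 1, n)
    rng.shuffle(grid)
    specs = []
    for i in range(n):
        n_c = int(rng.integers(nc_range[0], nc_range[1] + 1))
        lo_m = max(13.0 * n_c, config.mz_range[0] + 30.0)
        hi_m = min(21.0 * n_c, config.mz_range[1] - 30.0)
        if hi_m <= lo_m:
            hi_m = lo_m + 10.0
        mass = rng.uniform(lo_m, hi_m)
        k = int(rng.integers(n_species_range[0], n_species_range[1] + 1))
        species = [("[M+H]+", 1.0)]
        for ad in rng.choice(extra_pool, size=k - 1, replace=False):
            species.append((str(ad), float(rng.uniform(0.3, 1.0))))
        specs.append(
            MetaboliteSpec(
                neutral_mass=float(mass),
                n_c=n_c,
                rt_seconds=float(grid[i] * config.scan_interval_seconds),
                peak_sigma_scans=float(rng.uniform(3.0, 5.0)),
                base_abundance=float(rng.uniform(*abundance_range)),
                ion_species=tuple(species),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# mzML writing

def _b64(values: np.ndarray, dtype: str) -> tuple[str, int]:
    raw = np.asarray(values, dtype=dtype).tobytes()
    enc = base64.b64encode(raw).decode("ascii")
    return enc, len(enc)


_MZML_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
    '  <run id=%s>\n'
    '    <spectrumList count="%d">\n'
)


def write_run(run: Run, path: str | Path) -> None:
    """Write a Run as centroid mzML (m/z 64-bit, intensity 32-bit float).

    The output is readable by :func:`isopair.mz_io.read_run`; the
    round-trip is lossless to ≤1e-6 u in m/z, ≤1e-3 relative in intensity
    and 1e-4 s in retention time.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            _MZML_HEADER
            % (quoteattr(run.metadata.get("sample_id", "run")), len(run))
        )
        for spec in run:
            mz64, n1 = _b64(spec.mz, "<f8")
            in32, n2 = _b64(spec.intensity, "<f4")
            fh.write(
                f'      <spectrum index="{spec.scan_index}" '
                f'id="scan={spec.scan_index + 1}" '
                f'defaultArrayLength="{len(spec)}">\n'
                '        <cvParam cvRef="MS" accession="MS:1000511" '
                'name="ms level" value="1"/>\n'
                '        <cvParam cvRef="MS" accession="MS:1000127" '
                'name="centroid spectrum" value=""/>\n'
                '        <scanList count="1"><scan>\n'
                '          <cvParam cvRef="MS" accession="MS:1000016" '
                f'name="scan start time" value="{spec.rt_seconds:.4f}" '
                'unitName="second"/>\n'
                '        </scan></scanList>\n'
                '        <binaryDataArrayList count="2">\n'
                f'          <binaryDataArray encodedLength="{n1}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000523" '
                'name="64-bit float"/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression"/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000514" '
                'name="m/z array"/>\n'
                f'            <binary>{mz64}</binary>\n'
                '          </binaryDataArray>\n'
                f'          <binaryDataArray encodedLength="{n2}">\n'
                '            <cvParam cvRef="MS" accession="MS:1000521" '
                'name="32-bit float"/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000576" '
                'name="no compression"/>\n'
                '            <cvParam cvRef="MS" accession="MS:1000515" '
                'name="intensity array"/>\n'
                f'            <binary>{in32}</binary>\n'
                '          </binaryDataArray>\n'
                '        </binaryDataArrayList>\n'
                '      </spectrum>\n'
            )
        fh.write("    </spectrumList>\n  </run>\n</mzML>\n")
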