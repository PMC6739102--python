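"""Synthetic MALDI-TOF-like spectra with known taxon structure.

Each taxon is a template of Gaussian peaks on the 2-20 kDa instrument
range.  A configurable fraction of peak positions is shared by all taxa
(housekeeping-like masses); every taxon additionally carries exclusive
peaks, which guarantees at least one unique spectral feature between taxa
at default comparison parameters.  Replicate spectra of a taxon jitter the
peak positions (in ppm, emulating calibration drift between acquisitions)
and the amplitudes (lognormally, emulating spotting and ionization
variability), and add a non-negative noise floor.

Peak lists are emitted from the ground-truth jittered centroids with
S/N = amplitude / noise level, so the comparison machinery can be tested in
isolation from the wavelet peak caller; an end-to-end mode can instead
re-derive peak lists with :func:`maldiderep.preprocess.call_peaks_cwt`.

Randomness is a single integer seed fanned out into one independent stream
per (taxon, replicate), so any subset of the dataset is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import PeakList, RawSpectrum, MetadataTable, SpectrumDataset
from .preprocess import GridSpec, make_grid

import pandas as pd

__all__ = ["TaxonTemplate", "SynthConfig", "make_templates", "synth_spectrum", "synth_dataset"]


@dataclass(frozen=True)
class TaxonTemplate:
    """Ground-truth peak model of one taxon."""

    taxon_id: str
    peak_mzs: np.ndarray       # centroids, Da
    peak_amplitudes: np.ndarray
    peak_widths: np.ndarray    # Gaussian sigma, Da

    def __post_init__(self) -> None:
        mzs = np.asarray(self.peak_mzs, dtype=float)
        amps = np.asarray(self.peak_amplitudes, dtype=float)
        wids = np.asarray(self.peak_widths, dtype=float)
        object.__setattr__(self, "peak_mzs", mzs)
        object.__setattr__(self, "peak_amplitudes", amps)
        object.__setattr__(self, "peak_widths", wids)
        if not (mzs.size == amps.size == wids.size):
            raise ValueError("template arrays must have equal length")
        if np.any(amps <= 0) or np.any(wids <= 0):
            raise ValueError("amplitudes and widths must be positive")
        if mzs.size >= 2:
            gaps = np.diff(np.sort(mzs))
            if np.any(gaps <= 3.0 * wids.max()):
                raise ValueError("centroids must be separated by > 3x the max width")


def _default_grid() -> GridSpec:
    # 1 Da spacing over the 2-20 kDa instrument range
    return GridSpec(2000.0, 20000.0, 18001)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate clean replicate acquisitions.

    mz_jitter_sd: per-replicate centroid jitter in ppm of the centroid.
    amplitude_jitter_cv: coefficient of variation of the lognormal
        amplitude jitter.
    baseline_noise_sd: scale of the non-negative (folded-normal) noise
        floor, in intensity units.
    n_low_quality: degraded spectra appended to the dataset, each left with
        only ``n_strong_low`` peaks above the quality S/N cut-off.
    """

    n_taxa: int = 10
    replicates_per_taxon: int = 5
    n_peaks_per_taxon: int = 12
    shared_peak_fraction: float = 0.25
    mz_jitter_sd: float = 50.0          # ppm
    amplitude_jitter_cv: float = 0.15
    baseline_noise_sd: float = 0.5
    amplitude_min: float = 60.0
    amplitude_max: float = 200.0
    # peak width scales with m/z (constant resolving power, as in linear-mode
    # TOF): Gaussian sigma = mz / peak_resolution
    peak_resolution: float = 1800.0
    min_peak_separation: float = 60.0   # Da, across all templates
    n_low_quality: int = 0
    n_strong_low: int = 2
    low_quality_snr: float = 10.0
    strong_snr: float = 45.0
    grid: GridSpec = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.replicates_per_taxon < 1:
            raise ValueError("need at least one taxon and one replicate")
        if not 0.0 <= self.shared_peak_fraction < 1.0:
            raise ValueError("shared_peak_fraction must lie in [0, 1)")
        if self.mz_jitter_sd < 0 or self.amplitude_jitter_cv < 0:
            raise ValueError("jitter settings must be >= 0")
        if self.baseline_noise_sd < 0 or self.n_low_quality < 0:
            raise ValueError("noise and counts must be >= 0")


def _rng(cfg: SynthConfig, *key: int) -> np.random.Generator:
    # counter-based stream: one generator per (seed, *key)
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *key])


def make_templates(cfg: SynthConfig) -> list[TaxonTemplate]:
    """Draw taxon templates with a global shared peak set plus exclusive peaks.

    Every pair of taxa shares exactly ``floor(shared_peak_fraction *
    n_peaks_per_taxon)`` centroids; each taxon keeps >= 2 exclusive
    centroids.  All centroids (across taxa) respect the minimum separation,
    so exclusive peaks of one taxon fall on flat signal in every other.
    """
    n_shared = int(cfg.shared_peak_fraction * cfg.n_peaks_per_taxon)
    n_excl = cfg.n_peaks_per_taxon - n_shared
    if n_excl < 2:
        raise ValueError("each taxon needs >= 2 exclusive peaks; lower the shared fraction")
    n_total = n_shared + cfg.n_taxa * n_excl

    margin = 500.0  # keep correlation windows inside the grid
    lo, hi = cfg.grid.mz_min + margin, cfg.grid.mz_max - margin
    if (hi - lo) / cfg.min_peak_separation < n_total:
        raise ValueError("m/z range cannot hold the requested peaks at this separation")

    rng = _rng(cfg, 0, 0)
    positions: list[float] = []
    attempts = 0
    while len(positions) < n_total:
        attempts += 1
        if attempts > 200 * n_total:
            raise ValueError("could not place peaks with the requested separation")
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - p) > cfg.min_peak_separation for p in positions):
            positions.append(cand)
    positions_arr = np.array(positions)
    rng.shuffle(positions_arr)
    shared = positions_arr[:n_shared]

    templates = []
    for t in range(cfg.n_taxa):
        excl = positions_arr[n_shared + t * n_excl : n_shared + (t + 1) * n_excl]
        mzs = np.sort(np.concatenate([shared, excl]))
        amps = rng.uniform(cfg.amplitude_min, cfg.amplitude_max, size=mzs.size)
        templates.append(
            TaxonTemplate(
                taxon_id=f"taxon{t:02d}",
                peak_mzs=mzs,
                peak_amplitudes=amps,
                peak_widths=mzs / cfg.peak_resolution,
            )
        )
    return templates


def _render(
    grid: np.ndarray, mzs: np.ndarray, amps: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    signal = np.zeros_like(grid)
    for c, a, w in zip(mzs, amps, widths):
        lo = int(np.searchsorted(grid, c - 6 * w))
        hi = int(np.searchsorted(grid, c + 6 * w))
        signal[lo:hi] += a * np.exp(-((grid[lo:hi] - c) ** 2) / (2 * w**2))
    return signal


def synth_spectrum(
    template: TaxonTemplate,
    cfg: SynthConfig,
    replicate_index: int,
    taxon_index: int = 0,
    spectrum_id: str | None = None,
    amplitude_override: np.ndarray | None = None,
) -> tuple[RawSpectrum, PeakList]:
    """One replicate acquisition of a taxon: jittered signal plus noise.

    The returned peak list carries the jittered ground-truth centroids with
    S/N defined as amplitude over the noise scale.
    """
    sid = spectrum_id or f"{template.taxon_id}_r{replicate_index:02d}"
    rng = _rng(cfg, 1 + taxon_index, replicate_index)
    grid = make_grid(cfg.grid)

    mzs = template.peak_mzs * (
        1.0 + rng.normal(0.0, cfg.mz_jitter_sd * 1e-6, size=template.peak_mzs.size)
    )
    base_amps = (
        template.peak_amplitudes if amplitude_override is None else amplitude_override
    )
    if cfg.amplitude_jitter_cv > 0:
        sigma = float(np.sqrt(np.log1p(cfg.amplitude_jitter_cv**2)))
        amps = base_amps * rng.lognormal(-0.5 * sigma**2, sigma, size=base_amps.size)
    else:
        amps = np.asarray(base_amps, dtype=float).copy()

    signal = _render(grid, mzs, amps, template.peak_widths)
    if cfg.baseline_noise_sd > 0:
        signal = signal + np.abs(rng.normal(0.0, cfg.baseline_noise_sd, size=grid.size))

    noise_level = max(cfg.baseline_noise_sd, 1e-9)
    order = np.argsort(mzs)
    peaks = PeakList(sid, mzs[order], (amps / noise_level)[order])
    return RawSpectrum(sid, grid, signal), peaks


def synth_dataset(cfg: SynthConfig) -> tuple[SpectrumDataset, dict[str, str]]:
    """Full synthetic dataset plus ground-truth taxon label per spectrum.

    Emits ``n_taxa x replicates_per_taxon`` good spectra and
    ``n_low_quality`` degraded ones (templates reused round-robin, peak
    amplitudes rescaled so only ``n_strong_low`` peaks clear the strong-peak
    S/N cut-off).  Metadata uses the taxon id as the strain label.
    """
    templates = make_templates(cfg)
    records: dict[str, tuple[RawSpectrum, PeakList]] = {}
    truth: dict[str, str] = {}

    for t, template in enumerate(templates):
        for r in range(cfg.replicates_per_taxon):
            sid = f"{template.taxon_id}_r{r:02d}"
            raw, peaks = synth_spectrum(template, cfg, r, taxon_index=t, spectrum_id=sid)
            records[sid] = (raw, peaks)
            truth[sid] = template.taxon_id

    noise_level = max(cfg.baseline_noise_sd, 1e-9)
    for k in range(cfg.n_low_quality):
        template = templates[k % len(templates)]
        t = k % len(templates)
        sid = f"lowq{k:02d}_{template.taxon_id}"
        amps = np.full(template.peak_mzs.size, cfg.low_quality_snr * noise_level)
        amps[: cfg.n_strong_low] = cfg.strong_snr * noise_level
        raw, peaks = synth_spectrum(
            template,
            cfg,
            replicate_index=cfg.replicates_per_taxon + k,
            taxon_index=t,
            spectrum_id=sid,
            amplitude_override=amps,
        )
        records[sid] = (raw, peaks)
        truth[sid] = template.taxon_id

    meta = MetadataTable(
        pd.DataFrame(
            {"strain_label": [truth[sid] for sid in sorted(records)]},
            index=pd.Index(sorted(records), name="spectrum_id"),
        )
    )
    return SpectrumDataset(records=records, metadata=meta), truth
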