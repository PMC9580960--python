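"""Turn one MS/MS spectrum into a document of peak/loss words.

A *word* is a binned fragment peak (``peak@150.12``) or a neutral loss to
the precursor (``loss@50.00``). A *document* is the ordered multiset of
words extracted from one spectrum. Because words carry only mass
spectrometric information, everything downstream is independent of
retention time — the property that lets samples from different
chromatographic batches be compared directly.

The processing order is: relative-intensity filtering, minimum-peak-count
check, then binning of the surviving fragment m/z values and of the neutral
losses computed against the raw (unbinned) precursor m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

from .spectra_io import FragmentationSpectrum

#: Spectra-import defaults; shared by the CLI and the pipeline.
DEFAULT_MIN_RELATIVE_INTENSITY = 0.01
DEFAULT_MAX_RELATIVE_INTENSITY = 1.0
DEFAULT_MIN_PEAKS_REQUIRED = 10
DEFAULT_LOSSES_FROM = 10.0
DEFAULT_LOSSES_TO = 200.0
DEFAULT_N_DECIMALS = 2


@dataclass(frozen=True)
class ImportParams:
    """Spectra-import parameters.

    Parameters
    ----------
    min_relative_intensity, max_relative_intensity :
        Fragment peaks are kept when their intensity relative to the base
        (most intense) peak lies in ``[min, max]``; the base peak itself
        (relative intensity exactly 1) is kept under the default max of 1.
    min_peaks_required :
        Spectra with fewer surviving peaks than this are rejected outright;
        sparse spectra carry too little fragmentation information to
        fingerprint.
    losses_from, losses_to :
        Neutral-loss window in Da; a loss ``precursor_mz - fragment_mz`` is
        kept iff it lies in ``[losses_from, losses_to]`` (both inclusive).
    n_decimals :
        Binning resolution: m/z and loss values are rounded to this many
        decimals to form words.
    """

    min_relative_intensity: float = DEFAULT_MIN_RELATIVE_INTENSITY
    max_relative_intensity: float = DEFAULT_MAX_RELATIVE_INTENSITY
    min_peaks_required: int = DEFAULT_MIN_PEAKS_REQUIRED
    losses_from: float = DEFAULT_LOSSES_FROM
    losses_to: float = DEFAULT_LOSSES_TO
    n_decimals: int = DEFAULT_N_DECIMALS

    def __post_init__(self) -> None:
        if not 0 <= self.min_relative_intensity <= self.max_relative_intensity:
            raise ValueError("need 0 <= min_relative_intensity <= max_relative_intensity")
        if self.max_relative_intensity > 1:
            raise ValueError("max_relative_intensity is a fraction of the base peak, <= 1")
        if self.min_peaks_required < 1:
            raise ValueError("min_peaks_required must be >= 1")
        if not 0 < self.losses_from < self.losses_to:
            raise ValueError("need 0 < losses_from < losses_to")
        if self.n_decimals < 0:
            raise ValueError("n_decimals must be >= 0")


@dataclass(frozen=True)
class Rejected:
    """Sentinel for a spectrum that did not survive filtering (not an error)."""

    feature_id: str
    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class SpectralDocument:
    """Multiset of words extracted from one spectrum.

    Duplicate words (two peaks binning to the same value) are kept as
    multiple occurrences, because vectors count occurrences.
    """

    feature_id: str
    words: tuple[str, ...]
    source_sample: str = ""


def bin_value(value: float, n_decimals: int) -> str:
    """Round half-away-from-zero to ``n_decimals`` and format fixed-width.

    Uses decimal arithmetic on ``repr(value)`` so word strings are stable
    across platforms and locales (``round``/f-strings tie to even on the
    binary float and are therefore unsuitable for bin labels).
    """
    quantum = Decimal(1).scaleb(-n_decimals)
    return str(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def filter_spectrum(
    spectrum: FragmentationSpectrum, params: ImportParams | None = None
) -> FragmentationSpectrum | Rejected:
    """Scale intensities to the base peak and apply the intensity/count filters.

    Returns the spectrum with *relative* intensities and only the surviving
    peaks, or a :class:`Rejected` sentinel when no base peak exists (all
    intensities zero) or fewer than ``min_peaks_required`` peaks survive.
    """
    params = params or ImportParams()
    base = max((i for _, i in spectrum.peaks), default=0.0)
    if base <= 0:
        return Rejected(spectrum.feature_id, "no base peak")
    kept = tuple(
        (mz, i / base)
        for mz, i in spectrum.peaks
        if params.min_relative_intensity <= i / base <= params.max_relative_intensity
    )
    if len(kept) < params.min_peaks_required:
        return Rejected(
            spectrum.feature_id,
            f"too few peaks ({len(kept)} < {params.min_peaks_required})",
        )
    return replace(spectrum, peaks=kept)


def compute_losses(
    spectrum: FragmentationSpectrum, params: ImportParams | None = None
) -> list[tuple[float, float]]:
    """Neutral losses ``precursor_mz - fragment_mz`` within the loss window.

    Both window bounds are inclusive; each loss inherits the intensity of
    the fragment peak it came from. Losses are computed on the m/z axis
    (no charge correction).
    """
    params = params or ImportParams()
    out = []
    for mz, intensity in spectrum.peaks:
        loss = spectrum.precursor_mz - mz
        if params.losses_from <= loss <= params.losses_to:
            out.append((loss, intensity))
    return out


def spectrum_to_document(
    spectrum: FragmentationSpectrum, params: ImportParams | None = None
) -> SpectralDocument | Rejected:
    """Filter, bin and wordify one spectrum.

    Peak words come from the surviving fragment m/z values; loss words from
    the neutral losses of those same surviving peaks, binned on the loss
    value itself (not derived from binned peak words, to avoid compounding
    rounding error). Rejections from :func:`filter_spectrum` propagate.
    """
    params = params or ImportParams()
    filtered = filter_spectrum(spectrum, params)
    if isinstance(filtered, Rejected):
        return filtered
    words = [f"peak@{bin_value(mz, params.n_decimals)}" for mz, _ in filtered.peaks]
    words += [
        f"loss@{bin_value(loss, params.n_decimals)}"
        for loss, _ in compute_losses(filtered, params)
    ]
    return SpectralDocument(
        feature_id=spectrum.feature_id,
        words=tuple(words),
        source_sample=spectrum.source_sample,
    )


def documents_from_spectra(
    spectra: list[FragmentationSpectrum], params: ImportParams | None = None
) -> tuple[list[SpectralDocument], list[Rejected]]:
    """Convert a spectrum list, partitioning into documents and rejections."""
    docs: list[SpectralDocument] = []
    rejected: list[Rejected] = []
    for s in spectra:
        out = spectrum_to_document(s, params)
        (rejected if isinstance(out, Rejected) else docs).append(out)
    return docs, rejected
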