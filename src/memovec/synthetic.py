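"""Synthetic LC-MS/MS study generator with ground truth.

Emulates the statistical structure of the mixture evaluation design used
to assess retention-time-agnostic sample fingerprinting: a handful of
chemodiverse "parent" samples, binary and quaternary mixtures of them,
replicate injections, and acquisition batches that differ in retention-time
shift, detector sensitivity, and sub-bin m/z jitter. Blank injections carry
a dedicated contaminant panel so blank filtering has an observable effect.

Everything is deterministic given the design seed. Randomness that must be
shared across batches (which compounds a mixture yields, chromatographic
noise, m/z jitter draws) is keyed on (seed, composition, replicate,
compound) only, so two batches rendered from the same design differ exactly
by their declared batch parameters: an RT-shift-only batch pair produces
MGF files that differ in nothing but the RT field, and a lower-sensitivity
batch detects a strict subset of its partner's compounds.

The generator does not attempt chromatographic peak shapes, isotope
patterns or adducts: one compound yields one feature with one MS/MS
spectrum per sample in which it is detected.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .documents import DEFAULT_MIN_PEAKS_REQUIRED
from .spectra_io import (
    FeatureTable,
    FragmentationSpectrum,
    SampleMetadata,
    write_metadata,
    write_mgf,
)


@dataclass(frozen=True)
class CompoundTemplate:
    """Idealized compound: a precursor with a reproducible fragment pattern.

    Fragments are stored as (mass offset below the precursor in Da,
    relative intensity); fragment m/z values and the precursor sit exactly
    on the binning grid so that sub-bin m/z jitter never flips a word.
    """

    id: str
    precursor_mz: float
    fragments: tuple[tuple[float, float], ...]
    true_rt: float

    def __post_init__(self) -> None:
        if len(self.fragments) < DEFAULT_MIN_PEAKS_REQUIRED:
            raise ValueError(
                f"compound {self.id!r} has {len(self.fragments)} fragments; "
                f"needs >= {DEFAULT_MIN_PEAKS_REQUIRED} to survive import filtering"
            )
        for off, _ in self.fragments:
            if not 0 < off < self.precursor_mz:
                raise ValueError(
                    f"compound {self.id!r}: fragment offset {off} outside (0, precursor)"
                )


@dataclass(frozen=True)
class BatchEffect:
    """Acquisition batch parameters.

    rt_shift : systematic retention-time offset in seconds.
    sensitivity : multiplicative detector response in (0, 1]; scales
        intensities and lowers detection probabilities.
    mz_jitter_ppm : sd of fragment m/z error in ppm; the default 5 ppm stays
        below the 0.01 Da bin width for m/z < 1000, so words are stable.
    """

    name: str
    rt_shift: float = 0.0
    sensitivity: float = 1.0
    mz_jitter_ppm: float = 5.0


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a synthetic study.

    ``mixtures`` maps a composition name to parent weights (summing to 1);
    parents are named ``P1..Pn``. Detection of a compound in a sample is
    Bernoulli with probability logistic in log(weight x sensitivity):
    ``p = 1 / (1 + ((w s) / midpoint) ** -steepness)``, the simplest
    mechanism that yields sensitivity-dependent dropout while keeping a
    lower-sensitivity rendering a strict thinning of a higher one.
    """

    n_parents: int = 4
    compounds_per_parent: int = 30
    sharing_fraction: float = 0.1
    mixtures: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    batches: tuple[BatchEffect, ...] = (
        BatchEffect("C18", rt_shift=0.0, sensitivity=1.0),
        BatchEffect("C18-RTshift", rt_shift=120.0, sensitivity=0.85),
    )
    replicates: int = 3
    n_contaminants: int = 5
    seed: int = 42
    detection_midpoint: float = 0.02
    detection_steepness: float = 1.2
    rt_noise_sd: float = 2.0
    n_fragments_range: tuple[int, int] = (12, 24)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.mixtures:
            object.__setattr__(self, "mixtures", _default_mixtures(self.n_parents))
        names = [n for n, _ in self.mixtures]
        if len(set(names)) != len(names):
            raise ValueError("duplicate composition names in mixtures")
        for name, weights in self.mixtures:
            w = [v for _, v in weights]
            if any(v < 0 for v in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"mixture {name!r}: weights must be >= 0 and sum to 1")

    @property
    def parents(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.n_parents))


def _default_mixtures(n_parents: int):
    """Parents alone, all binary pairs at 60/40, and one equal-parts mixture."""
    parents = [f"P{i + 1}" for i in range(n_parents)]
    out = [(p, ((p, 1.0),)) for p in parents]
    for i in range(n_parents):
        for j in range(i + 1, n_parents):
            out.append((f"{parents[i]}+{parents[j]}", ((parents[i], 0.6), (parents[j], 0.4))))
    if n_parents > 2:  # with 2 parents this would duplicate the binary pair
        out.append(("+".join(parents), tuple((p, 1.0 / n_parents) for p in parents)))
    return tuple(out)


def _h(text: str) -> int:
    """Stable 32-bit hash for seeding (crc32 is platform-independent)."""
    return zlib.crc32(text.encode("utf-8"))


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng([e & 0x7FFFFFFF for e in entropy])


# ---------------------------------------------------------------------------
# compound library


def generate_library(
    n_compounds: int,
    n_fragments_range: tuple[int, int] = (12, 24),
    seed: int = 0,
    mz_range: tuple[float, float] = (150.0, 850.0),
    rt_range: tuple[float, float] = (30.0, 420.0),
    prefix: str = "cmpd",
) -> list[CompoundTemplate]:
    """Draw a deterministic library of compound templates.

    Each compound gets a precursor m/z on the 0.01 Da grid, a true retention
    time inside the gradient, and fragment offsets strictly below the
    precursor with at least one inside the 10-200 Da neutral-loss window so
    every compound contributes loss words as well as peak words.
    """
    lo, hi = n_fragments_range
    if lo < DEFAULT_MIN_PEAKS_REQUIRED:
        raise ValueError(
            f"minimum fragment count {lo} is below the import filter "
            f"threshold {DEFAULT_MIN_PEAKS_REQUIRED}; such compounds could never be seen"
        )
    if n_compounds < 0 or lo > hi:
        raise ValueError("infeasible library parameters")
    rng = _rng(seed, _h("library"))
    library = []
    for i in range(n_compounds):
        precursor = round(float(rng.uniform(*mz_range)), 2)
        n_frag = int(rng.integers(lo, hi + 1))
        offsets: list[float] = []
        seen: set[float] = set()
        while len(offsets) < n_frag:
            # first offset forced into the neutral-loss window (clipped for
            # light precursors so the fragment m/z stays comfortably positive)
            low, high = (10.0, min(200.0, precursor - 50.0)) if not offsets else (5.0, precursor - 50.0)
            off = round(float(rng.uniform(low, high)), 2)
            if off not in seen:
                seen.add(off)
                offsets.append(off)
        rel = rng.uniform(0.05, 1.0, size=n_frag)
        rel[int(rng.integers(n_frag))] = 1.0  # one base peak
        library.append(
            CompoundTemplate(
                id=f"{prefix}{i:04d}",
                precursor_mz=precursor,
                fragments=tuple(zip(offsets, np.round(rel, 4).tolist())),
                true_rt=round(float(rng.uniform(*rt_range)), 1),
            )
        )
    return library


# ---------------------------------------------------------------------------
# study assembly


@dataclass(frozen=True)
class SyntheticStudy:
    """In-memory rendered study: spectra, metadata, and ground truth."""

    design: StudyDesign
    library: tuple[CompoundTemplate, ...]
    compound_parents: dict[str, tuple[str, ...]]  # compound -> parents carrying it
    spectra: dict[str, list[FragmentationSpectrum]]
    metadata: list[SampleMetadata]
    truth: dict[str, tuple[str, ...]]  # sample -> detected compound ids

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.metadata]

    @property
    def blank_ids(self) -> list[str]:
        return [m.sample_id for m in self.metadata if m.is_blank]

    def factor(self, name: str) -> dict[str, str]:
        return {m.sample_id: m.factors[name] for m in self.metadata if not m.is_blank}


def _detection_probability(ws: float, design: StudyDesign) -> float:
    if ws <= 0:
        return 0.0
    return 1.0 / (1.0 + (ws / design.detection_midpoint) ** -design.detection_steepness)


def _compound_weight(
    compound_id: str,
    weights: Mapping[str, float],
    compound_parents: Mapping[str, tuple[str, ...]],
) -> float:
    return min(1.0, sum(weights.get(p, 0.0) for p in compound_parents[compound_id]))


def render_sample(
    design: StudyDesign,
    composition: str,
    weights: Mapping[str, float],
    batch: BatchEffect,
    replicate: int,
    library: Sequence[CompoundTemplate],
    compound_parents: Mapping[str, tuple[str, ...]],
    sample_id: str,
    force_include: frozenset[str] = frozenset(),
) -> tuple[list[FragmentationSpectrum], tuple[str, ...]]:
    """Render one sample: which compounds are detected, and their spectra.

    All random draws are keyed on (seed, composition, replicate, compound) —
    never on the batch — so identical batch parameters reproduce identical
    spectra and batch effects act as pure deterministic transforms.
    """
    spectra: list[FragmentationSpectrum] = []
    detected: list[str] = []
    feature_index = 1
    for compound in library:
        rng = _rng(design.seed, _h(composition), replicate, _h(compound.id))
        u = float(rng.uniform())
        ws = _compound_weight(compound.id, weights, compound_parents)
        p = _detection_probability(ws * batch.sensitivity, design)
        if compound.id not in force_include and u >= p:
            continue
        detected.append(compound.id)
        z_rt = float(rng.standard_normal())
        amount = float(rng.lognormal(mean=0.0, sigma=0.3)) * 1e6 * max(ws, 1e-3)
        z_mz = rng.standard_normal(len(compound.fragments))
        rt = compound.true_rt + z_rt * design.rt_noise_sd + batch.rt_shift
        peaks = []
        for k, (offset, rel) in enumerate(compound.fragments):
            mz = compound.precursor_mz - offset
            mz *= 1.0 + z_mz[k] * batch.mz_jitter_ppm * 1e-6
            peaks.append((mz, rel * amount * batch.sensitivity))
        spectra.append(
            FragmentationSpectrum(
                feature_id=f"{sample_id}_f{feature_index}",
                precursor_mz=compound.precursor_mz,
                peaks=tuple(sorted(peaks)),
                retention_time=rt,
                charge=1,
                source_sample=sample_id,
            )
        )
        feature_index += 1
    return spectra, tuple(detected)


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Render the full study in memory: all mixtures x batches x replicates.

    Adds one blank injection per batch carrying the full contaminant panel;
    contaminants are also spiked (weight 1) into every real sample so that
    blank filtering visibly shrinks the vocabulary. Sample metadata carries
    the two grouping factors of the evaluation design: ``experiment`` (the
    batch) and ``composition`` (the mixture).
    """
    library = generate_library(
        design.n_parents * design.compounds_per_parent,
        design.n_fragments_range,
        seed=design.seed,
    )
    contaminants = generate_library(
        design.n_contaminants, design.n_fragments_range, seed=design.seed + 1, prefix="contam"
    )
    share_rng = _rng(design.seed, _h("sharing"))
    compound_parents: dict[str, tuple[str, ...]] = {}
    parents = design.parents
    for i, compound in enumerate(library):
        owners = [parents[i % design.n_parents]]
        if design.n_parents > 1 and share_rng.uniform() < design.sharing_fraction:
            other = parents[int(share_rng.integers(design.n_parents - 1))]
            if other == owners[0]:
                other = parents[-1]
            owners.append(other)
        compound_parents[compound.id] = tuple(owners)
    for c in contaminants:
        compound_parents[c.id] = parents  # background: present whatever the mixture

    full_library = list(library) + list(contaminants)
    contaminant_ids = frozenset(c.id for c in contaminants)

    spectra: dict[str, list[FragmentationSpectrum]] = {}
    metadata: list[SampleMetadata] = []
    truth: dict[str, tuple[str, ...]] = {}
    for composition, weight_items in design.mixtures:
        weights = dict(weight_items)
        for batch in design.batches:
            for rep in range(1, design.replicates + 1):
                sid = f"{composition}_{batch.name}_r{rep}"
                s, detected = render_sample(
                    design, composition, weights, batch, rep,
                    full_library, compound_parents, sid,
                )
                spectra[sid] = s
                truth[sid] = detected
                metadata.append(
                    SampleMetadata(
                        sample_id=sid,
                        factors={"experiment": batch.name, "composition": composition},
                        is_blank=False,
                    )
                )
    for batch in design.batches:
        sid = f"blank_{batch.name}"
        s, detected = render_sample(
            design, "blank", {}, batch, 0, contaminants, compound_parents, sid,
            force_include=contaminant_ids,
        )
        spectra[sid] = s
        truth[sid] = detected
        metadata.append(
            SampleMetadata(
                sample_id=sid,
                factors={"experiment": batch.name, "composition": "blank"},
                is_blank=True,
            )
        )
    return SyntheticStudy(
        design=design,
        library=tuple(full_library),
        compound_parents=compound_parents,
        spectra=spectra,
        metadata=metadata,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write one MGF per sample plus metadata.csv and truth.csv.

    Output is byte-stable for a given design (fixed float formatting), so
    the same seed always yields an identical directory tree.
    """
    outdir = Path(outdir)
    mgf_dir = outdir / "mgf"
    mgf_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid in sorted(study.spectra):
        p = mgf_dir / f"{sid}.mgf"
        write_mgf(study.spectra[sid], p)
        paths[sid] = p
    write_metadata(study.metadata, outdir / "metadata.csv")
    with open(outdir / "truth.csv", "w", encoding="utf-8") as fh:
        fh.write("sample_id,compound_id\n")
        for sid in sorted(study.truth):
            for cid in study.truth[sid]:
                fh.write(f"{sid},{cid}\n")
    return paths


# ---------------------------------------------------------------------------
# feature-intensity baseline (what RT-based alignment would produce)


def naive_feature_table(
    study: SyntheticStudy,
    mz_tol: float = 0.01,
    rt_tol: float = 30.0,
    include_blanks: bool = False,
) -> FeatureTable:
    """Align the study's features by (precursor m/z, RT) into an intensity table.

    Emulates the classical join-alignment a feature-based workflow performs:
    features agreeing in precursor bin and retention time (single-linkage
    within ``rt_tol`` seconds) become one aligned feature. A batch RT shift
    larger than ``rt_tol`` therefore splits the same compound into separate
    per-batch features — exactly the failure mode that inflates apparent
    between-batch distances in intensity-based comparisons.
    """
    samples = [
        m.sample_id for m in study.metadata if include_blanks or not m.is_blank
    ]
    records = []  # (mz_bin, rt, sample, area)
    for sid in samples:
        for spec in study.spectra[sid]:
            area = float(sum(i for _, i in spec.peaks))
            records.append((round(spec.precursor_mz / mz_tol) * mz_tol, spec.retention_time, sid, area))
    # group by precursor bin, then chain RT values within rt_tol
    by_mz: dict[float, list[tuple[float, str, float]]] = {}
    for mz_bin, rt, sid, area in records:
        by_mz.setdefault(round(mz_bin, 6), []).append((rt, sid, area))
    feature_ids: list[str] = []
    columns: dict[str, dict[str, float]] = {}
    for mz_bin in sorted(by_mz):
        group = sorted(by_mz[mz_bin])
        cluster: list[tuple[float, str, float]] = []
        clusters: list[list[tuple[float, str, float]]] = []
        for item in group:
            if cluster and item[0] - cluster[-1][0] > rt_tol:
                clusters.append(cluster)
                cluster = []
            cluster.append(item)
        if cluster:
            clusters.append(cluster)
        for c in clusters:
            rt_mean = sum(r for r, _, _ in c) / len(c)
            fid = f"{mz_bin:.2f}@{rt_mean:.0f}s"
            if fid in columns:  # rare collision: merge
                for _, sid, area in c:
                    columns[fid][sid] = columns[fid].get(sid, 0.0) + area
                continue
            feature_ids.append(fid)
            columns[fid] = {}
            for _, sid, area in c:
                columns[fid][sid] = columns[fid].get(sid, 0.0) + area
    values = np.zeros((len(feature_ids), len(samples)))
    col_of = {s: j for j, s in enumerate(samples)}
    for i, fid in enumerate(feature_ids):
        for sid, area in columns[fid].items():
            values[i, col_of[sid]] = area
    return FeatureTable(feature_ids=tuple(feature_ids), sample_ids=tuple(samples), values=values)
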