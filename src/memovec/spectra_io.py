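"""Readers and writers for the formats the workflow touches.

Per-sample MGF files (Mascot Generic Format) carry the MS/MS spectra from
which fingerprints are built; GNPS-FBMN quant tables carry aligned feature
intensities for the aligned route; a small metadata table carries sample
grouping factors and blank flags; fingerprint matrices are persisted as
plain CSV (wide or sparse-triplet dialect).

MGF parsing is delegated to :mod:`pyteomics.mgf`; this module layers the
dialect tolerance (RTINSECONDS/RTINMINUTES, FEATURE_ID/SCANS/TITLE identity)
and the validation the pipeline relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics.auxiliary import PyteomicsError


class MgfFormatError(ValueError):
    """A spectrum block that cannot be interpreted."""


@dataclass(frozen=True)
class FragmentationSpectrum:
    """One feature's MS/MS scan.

    Parameters
    ----------
    feature_id :
        Identifier of the feature the scan belongs to.
    precursor_mz :
        Precursor ion m/z in Thomson; must be positive.
    peaks :
        ``(mz, intensity)`` pairs, sorted ascending by m/z. Intensities are
        arbitrary detector counts (or relative intensities after filtering).
    retention_time :
        Chromatographic retention time in seconds, if known. The fingerprint
        never depends on it.
    charge :
        Precursor charge state, if reported.
    source_sample :
        Sample the scan was acquired in.
    """

    feature_id: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    retention_time: float | None = None
    charge: int | None = None
    source_sample: str = ""

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(
                f"precursor_mz must be positive, got {self.precursor_mz!r} "
                f"(feature {self.feature_id!r})"
            )
        pk = tuple((float(m), float(i)) for m, i in self.peaks)
        if any(m <= 0 for m, _ in pk):
            raise ValueError(f"non-positive fragment m/z in feature {self.feature_id!r}")
        if any(i < 0 for _, i in pk):
            raise ValueError(f"negative intensity in feature {self.feature_id!r}")
        if any(pk[j][0] > pk[j + 1][0] for j in range(len(pk) - 1)):
            pk = tuple(sorted(pk))
        object.__setattr__(self, "peaks", pk)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])

    def with_retention_time(self, rt: float | None) -> "FragmentationSpectrum":
        return replace(self, retention_time=rt)


@dataclass(frozen=True)
class FeatureTable:
    """Aligned feature x sample intensity table (areas or heights, >= 0).

    Zero means the feature was not detected in the sample; downstream code
    only ever uses presence/absence, never the magnitudes.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_features, n_samples)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (values < 0).any():
            raise ValueError("feature intensities must be non-negative")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "values", values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Grouping information for one sample (factor name -> level)."""

    sample_id: str
    factors: dict[str, str] = field(default_factory=dict)
    is_blank: bool = False


# ---------------------------------------------------------------------------
# MGF


def _rt_seconds(params: dict) -> float | None:
    if "rtinseconds" in params:
        return float(params["rtinseconds"])
    if "rtinminutes" in params:
        return float(params["rtinminutes"]) * 60.0
    return None


def _feature_identity(params: dict, block_index: int) -> str:
    for key in ("feature_id", "scans", "title"):
        if key in params and str(params[key]).strip():
            return str(params[key]).strip()
    return str(block_index)


def read_mgf(path: str | os.PathLike, sample_id: str | None = None) -> list[FragmentationSpectrum]:
    """Read all spectra from one MGF file.

    ``PEPMASS`` supplies the precursor m/z; ``RTINSECONDS`` (or
    ``RTINMINUTES``, converted) the retention time; ``FEATURE_ID``, ``SCANS``
    or ``TITLE`` — in that priority order — the feature identity. Peak lines
    are whitespace-separated ``mz intensity``; extra columns are ignored.

    Parameters
    ----------
    path :
        MGF file with ``BEGIN IONS``/``END IONS`` blocks. An empty file
        yields an empty list.
    sample_id :
        Sample to attribute spectra to; defaults to the file's stem.

    Raises
    ------
    MgfFormatError
        On a block with a missing or non-numeric ``PEPMASS`` or an
        unparseable peak line, naming the (0-based) block index.
    """
    sample = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    spectra: list[FragmentationSpectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except (PyteomicsError, ValueError) as exc:
                raise MgfFormatError(f"malformed MGF block {index} in {path}: {exc}") from exc
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise MgfFormatError(f"malformed MGF block {index} in {path}: missing PEPMASS")
            charge = params.get("charge")
            spectra.append(
                FragmentationSpectrum(
                    feature_id=_feature_identity(params, index),
                    precursor_mz=float(pepmass[0]),
                    peaks=tuple(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                    retention_time=_rt_seconds(params),
                    charge=int(charge[0]) if charge else None,
                    source_sample=sample,
                )
            )
            index += 1
    return spectra


def write_mgf(spectra: Iterable[FragmentationSpectrum], path: str | os.PathLike) -> None:
    """Write spectra as MGF, emitting FEATURE_ID and RTINSECONDS headers."""
    entries = []
    for s in spectra:
        params: dict = {"feature_id": s.feature_id, "pepmass": (s.precursor_mz,)}
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensities,
            }
        )
    _mgf.write(
        entries,
        output=str(path),
        key_order=["feature_id", "pepmass", "rtinseconds", "charge"],
        fragment_format="%.6f %.6f",
        write_charges=False,
        file_mode="w",
    )


# ---------------------------------------------------------------------------
# GNPS-FBMN quant table

_ROW_ID = "row ID"
_AREA_SUFFIX = " Peak area"


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    """Read a GNPS-FBMN quant CSV into a :class:`FeatureTable`.

    Expects a ``row ID`` column and one ``<sample> Peak area`` column per
    sample (``row m/z`` / ``row retention time`` columns are ignored). Values
    are loaded as-is; presence/absence is decided downstream, never here.
    """
    df = pd.read_csv(path)
    if _ROW_ID not in df.columns:
        raise MgfFormatError(f"feature table {path} lacks a '{_ROW_ID}' column")
    ids = df[_ROW_ID].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise MgfFormatError(f"feature table {path} has duplicated row ID(s): {', '.join(dup)}")
    sample_cols = [c for c in df.columns if c.endswith(_AREA_SUFFIX)]
    samples = [c[: -len(_AREA_SUFFIX)].strip() for c in sample_cols]
    values = df[sample_cols].to_numpy(dtype=float) if sample_cols else np.zeros((len(df), 0))
    return FeatureTable(feature_ids=tuple(ids), sample_ids=tuple(samples), values=values)


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a :class:`FeatureTable` in the GNPS-FBMN quant dialect."""
    df = pd.DataFrame({_ROW_ID: list(table.feature_ids)})
    for j, s in enumerate(table.sample_ids):
        df[f"{s}{_AREA_SUFFIX}"] = table.values[:, j]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Metadata


def read_metadata(path: str | os.PathLike) -> list[SampleMetadata]:
    """Read a sample metadata table (CSV, or TSV by extension).

    Requires a ``sample_id`` column; an optional boolean-ish ``is_blank``
    column flags blanks; every other column is a grouping factor.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise MgfFormatError(f"metadata table {path} lacks a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise MgfFormatError(f"metadata table {path} has duplicated sample_id values")
    factor_cols = [c for c in df.columns if c not in ("sample_id", "is_blank")]
    records = []
    for _, row in df.iterrows():
        blank = str(row.get("is_blank", "")).strip().lower() in ("1", "true", "yes")
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                factors={c: row[c] for c in factor_cols},
                is_blank=blank,
            )
        )
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | os.PathLike) -> None:
    factor_cols: list[str] = []
    for r in records:
        for c in r.factors:
            if c not in factor_cols:
                factor_cols.append(c)
    rows = [
        {"sample_id": r.sample_id, **{c: r.factors.get(c, "") for c in factor_cols},
         "is_blank": r.is_blank}
        for r in records
    ]
    pd.DataFrame(rows, columns=["sample_id", *factor_cols, "is_blank"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fingerprint matrix persistence (wide and triplet CSV dialects)


def write_matrix(matrix, path: str | os.PathLike, dialect: str = "wide") -> None:
    """Persist a fingerprint matrix as CSV.

    ``wide``: rows = samples, columns = words, first column ``sample_id`` —
    human-inspectable and diff-able. ``triplet``: ``sample_id,word,count``
    rows for the nonzero entries only, better for very wide matrices. A
    leading ``# normalized=...`` comment records the normalization flag.
    """
    if dialect not in ("wide", "triplet"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# normalized={matrix.normalized}\n")
        if dialect == "wide":
            df = matrix.to_dataframe()
            df.index.name = "sample_id"
            df.to_csv(fh)
        else:
            coo = matrix.counts.tocoo()
            df = pd.DataFrame(
                {
                    "sample_id": [matrix.sample_ids[i] for i in coo.row],
                    "word": [matrix.vocabulary[j] for j in coo.col],
                    "count": coo.data,
                }
            )
            df.to_csv(fh, index=False)
            # trailer preserves sample order incl. rows with no nonzero entry
            fh.write("# samples=" + "|".join(matrix.sample_ids) + "\n")


def read_matrix(path: str | os.PathLike):
    """Read a fingerprint matrix written by :func:`write_matrix` (either dialect)."""
    from .matrix import MemoMatrix

    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("# normalized="):
        raise MgfFormatError(f"{path} is not a persisted fingerprint matrix")
    normalized = first.strip().split("=", 1)[1] == "True"
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()[1:]
    trailer = [ln for ln in lines if ln.startswith("# samples=")]
    body = [ln for ln in lines if not ln.startswith("#")]
    import io

    df = pd.read_csv(io.StringIO("".join(body)))
    if list(df.columns[:3]) == ["sample_id", "word", "count"] and len(df.columns) == 3:
        order = trailer[0].strip().split("=", 1)[1].split("|") if trailer else []
        order = [s for s in order if s]
        vectors: dict[str, dict[str, float]] = {s: {} for s in order}
        for _, row in df.iterrows():
            vectors.setdefault(str(row["sample_id"]), {})[str(row["word"])] = float(row["count"])
        return MemoMatrix.from_counts(vectors, normalized=normalized)
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return MemoMatrix.from_dataframe(df, normalized=normalized)
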