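"""End-to-end run: spectra -> documents -> matrix -> distances -> tests.

`run_pipeline` chains the stages with one config object, writes every
artifact with a machine-readable manifest, and logs per-stage counts so
filter-order questions can be debugged from the log alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .documents import ImportParams, documents_from_spectra
from .matrix import MemoMatrix, filter_blanks, matrix_from_aligned, matrix_from_unaligned, normalize_samplewise
from .spectra_io import read_feature_table, read_metadata, read_mgf, write_matrix
from .stats import PermanovaResult, bray_curtis, pcoa, permanova

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (detected before any work starts)."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    route : ``"unaligned"`` (one MGF per sample) or ``"aligned"``
        (one aligned MGF + feature quant table).
    mgf_paths : per-sample MGF files (unaligned) or the single aligned MGF.
    feature_table_path : quant CSV, required for the aligned route.
    metadata_path : optional sample metadata (blank flags + factors).
    blank_ids : explicit blank sample ids (merged with metadata flags).
    normalize : scale rows to relative frequencies before distances.
    permanova_factors : metadata factor columns to test.
    """

    route: str = "unaligned"
    mgf_paths: list[str] = field(default_factory=list)
    feature_table_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "memovec_out"
    params: ImportParams = field(default_factory=ImportParams)
    blank_ids: list[str] = field(default_factory=list)
    normalize: bool = False
    permanova_factors: list[str] = field(default_factory=list)
    n_permutations: int = 999
    seed: int = 0

    def validate(self) -> None:
        if self.route not in ("unaligned", "aligned"):
            raise ConfigError(f"unknown route {self.route!r}")
        if self.route == "aligned" and not self.feature_table_path:
            raise ConfigError("route 'aligned' requires a feature table path")
        if not self.mgf_paths:
            raise ConfigError("no MGF input files given")
        if self.route == "aligned" and len(self.mgf_paths) != 1:
            raise ConfigError("route 'aligned' takes exactly one (aligned) MGF file")
        if self.permanova_factors and not self.metadata_path:
            raise ConfigError("PERMANOVA factors require a metadata table")


@dataclass
class RunResult:
    matrix: MemoMatrix
    distance_matrix: object
    ordination: object
    permanova_results: list[PermanovaResult]
    manifest: dict


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured run and write all artifacts to ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    metadata = read_metadata(config.metadata_path) if config.metadata_path else []
    blanks = set(config.blank_ids) | {m.sample_id for m in metadata if m.is_blank}

    rejected_total = 0
    if config.route == "unaligned":
        samples = {}
        for path in config.mgf_paths:
            spectra = read_mgf(path)
            if not spectra:
                logger.warning("stage read_mgf: %s contains no spectra", path)
                continue
            sid = spectra[0].source_sample
            docs, rejected = documents_from_spectra(spectra, config.params)
            rejected_total += len(rejected)
            logger.info(
                "stage documents: sample %s: %d spectra, %d rejected, %d words",
                sid, len(spectra), len(rejected), sum(len(d.words) for d in docs),
            )
            samples[sid] = docs
        matrix = matrix_from_unaligned(samples)
    else:
        spectra = read_mgf(config.mgf_paths[0])
        table = read_feature_table(config.feature_table_path)
        docs, rejected = documents_from_spectra(spectra, config.params)
        rejected_total += len(rejected)
        matrix = matrix_from_aligned({d.feature_id: d for d in docs}, table)
    logger.info("stage matrix: %d samples x %d words", *matrix.shape)

    known_blanks = blanks & set(matrix.sample_ids)
    if known_blanks:
        matrix = filter_blanks(matrix, known_blanks)
        logger.info("stage filter_blanks: %d samples x %d words remain", *matrix.shape)
    if config.normalize:
        matrix = normalize_samplewise(matrix)

    dm = bray_curtis(matrix)
    ordination = pcoa(dm)
    tests: list[PermanovaResult] = []
    grouping_by_factor = {
        factor: {m.sample_id: m.factors.get(factor, "") for m in metadata}
        for factor in config.permanova_factors
    }
    for factor, grouping in grouping_by_factor.items():
        tests.append(
            permanova(
                dm,
                {s: grouping[s] for s in dm.ids},
                factor=factor,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
        )

    write_matrix(matrix, out / "memo_matrix.csv")
    dm.write(str(out / "distance_matrix.csv"))
    ordination.samples.to_csv(out / "pcoa_coordinates.csv")
    with open(out / "permanova.csv", "w", encoding="utf-8") as fh:
        fh.write("factor,pseudo_F,p_value,n_permutations,n_samples,n_groups\n")
        for t in tests:
            fh.write(
                f"{t.grouping_factor},{t.pseudo_F:.6g},{t.p_value:.6g},"
                f"{t.n_permutations},{t.n_samples},{t.n_groups}\n"
            )
    manifest = {
        "memovec_version": __version__,
        "route": config.route,
        "params": asdict(config.params),
        "normalize": config.normalize,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "blank_ids": sorted(blanks),
        "inputs": {Path(p).name: _digest(p) for p in config.mgf_paths},
        "n_samples": matrix.shape[0],
        "n_words": matrix.shape[1],
        "n_spectra_rejected": rejected_total,
    }
    if config.feature_table_path:
        manifest["inputs"][Path(config.feature_table_path).name] = _digest(
            config.feature_table_path
        )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(matrix, dm, ordination, tests, manifest)
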