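"""End-to-end pipeline: import -> calibrate -> stack -> mask -> correlate -> score.

One :class:`RunConfig` drives a full run; every stage is also exposed as a
CLI subcommand (see :mod:`hsqcstocsy.cli`) operating on the same on-disk
artifacts, so a staged run composes to the same result as :func:`run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import re
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bruker_io, correlation, dataset, identify, synthetic
from .errors import ConfigError, HsqcStocsyError

__all__ = ["RunConfig", "PeakRequest", "run_pipeline", "load_config"]


@dataclasses.dataclass(frozen=True)
class PeakRequest:
    metabolite: str
    ppm_h: float
    ppm_c: float
    cutoff: float


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: Path
    # exactly one input source: bruker directories, a portable container, or
    # a synthetic simulation request {"n_samples": int, ...}
    bruker_dirs: list[Path] | None = None
    portable_path: Path | None = None
    simulate: dict[str, Any] | None = None
    calibrate: bool = True
    reference_ppm: tuple[float, float] = (0.0, 0.0)
    normalize: bool = False  # optional step, off by default
    noise_threshold: float | None = None  # explicit, else multiplier * MAD
    noise_multiplier: float = 5.0
    peaks: list[PeakRequest] = dataclasses.field(default_factory=list)
    singletons: list[tuple[str, float, float]] = dataclasses.field(default_factory=list)
    tolerances: tuple[float, float] = identify.DEFAULT_TOLERANCES
    reference_csv: Path | None = None
    seed: int = 0

    def __post_init__(self):
        sources = [
            s for s in (self.bruker_dirs, self.portable_path, self.simulate)
            if s is not None
        ]
        if len(sources) != 1:
            raise ConfigError(
                "exactly one input source (bruker_dirs, portable_path or simulate) "
                "must be given"
            )
        for p in self.peaks:
            if not -1.0 <= p.cutoff <= 1.0:
                raise ConfigError(
                    f"cutoff {p.cutoff} for '{p.metabolite}' outside [-1, 1]"
                )
        if self.noise_threshold is not None:
            # YAML 1.1 parses bare "1e9" as a string; coerce defensively
            self.noise_threshold = float(self.noise_threshold)
            if self.noise_threshold < 0:
                raise ConfigError("noise_threshold must be >= 0")
        if any(t <= 0 for t in self.tolerances):
            raise ConfigError("tolerances must be positive")
        for path in (self.portable_path, self.reference_csv):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"path does not exist: {path}")
        for d in self.bruker_dirs or []:
            if not Path(d).is_dir():
                raise ConfigError(f"Bruker directory does not exist: {d}")


def load_config(path: Path | str) -> RunConfig:
    """Build a RunConfig from a YAML/JSON mapping with the same field names."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must hold a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "peaks" in raw:
        raw["peaks"] = [PeakRequest(**p) for p in raw["peaks"]]
    if "singletons" in raw:
        raw["singletons"] = [tuple(s) for s in raw["singletons"]]
    for key in ("output_dir", "portable_path", "reference_csv"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    if raw.get("bruker_dirs") is not None:
        raw["bruker_dirs"] = [Path(d) for d in raw["bruker_dirs"]]
    for key in ("reference_ppm", "tolerances"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def slugify(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name).strip("_")


def _stage(log: list, name: str, **info):
    log.append({"stage": name, **info})


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all outputs to ``config.output_dir``.

    Outputs: the stacked dataset as a portable container, one correlation
    plot per requested peak (Bruker directory + peak CSV + plot container),
    a merged constructed spectrum, a recovery CSV when references are
    available, and a ``manifest.json`` echoing the configuration and the
    per-stage log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    ground_truth_refs = None

    stage = "import"
    try:
        if config.simulate is not None:
            args = dict(config.simulate)
            args.setdefault("seed", config.seed)
            model = synthetic.default_model(**args)
            bundle = synthetic.generate_dataset(model, synthetic.default_grid())
            spectra = bundle.spectra
            bundle.ground_truth.to_csv(out / "ground_truth.csv", index=False)
            bundle.concentrations.to_csv(out / "concentrations.csv")
            ground_truth_refs = {
                r.metabolite: r
                for r in synthetic.library_to_references(model.metabolites)
            }
        elif config.portable_path is not None:
            spectra = bruker_io.read_portable(config.portable_path)
        else:
            spectra = [bruker_io.read_bruker_processed(d) for d in config.bruker_dirs]
        _stage(log, stage, n_spectra=len(spectra))

        stage = "calibrate"
        if config.calibrate:
            spectra = [
                dataset.calibrate_to_reference(s, reference_ppm=config.reference_ppm)
                for s in spectra
            ]
            _stage(log, stage, reference_ppm=list(config.reference_ppm))

        stage = "normalize"
        if config.normalize:
            spectra = [dataset.normalize_total_intensity(s) for s in spectra]
            _stage(log, stage)

        stage = "stack"
        bruker_io.write_portable(spectra, out / "dataset.h5")
        matrix = dataset.stack(spectra)
        _stage(log, stage, n=matrix.n, k_total=matrix.k_total)

        stage = "mask-noise"
        threshold = (
            config.noise_threshold
            if config.noise_threshold is not None
            else dataset.suggest_noise_threshold(matrix, config.noise_multiplier)
        )
        matrix = dataset.apply_noise_exclusion(matrix, threshold)
        dataset.save_matrix(matrix, out / "matrix.h5")
        _stage(log, stage, threshold=threshold, k_kept=matrix.k_kept)

        stage = "correlate"
        scaled = correlation.autoscale(matrix)
        plots_dir = out / "plots"
        plots_dir.mkdir(exist_ok=True)
        cut_plots = []
        for req in config.peaks:
            selection = identify.select_peak(matrix, (req.ppm_h, req.ppm_c))
            plot = correlation.correlate_peak(scaled, selection)
            plot.label = req.metabolite
            plot = correlation.apply_cutoff(plot, req.cutoff)
            cut_plots.append(plot)
            slug = slugify(req.metabolite)
            correlation.save_plot(plot, plots_dir / f"{slug}.h5")
            bruker_io.write_bruker_processed(
                plot.to_spectrum(), plots_dir / slug, value_scale=1e6
            )
            identify.extract_plot_peaks(plot).to_csv(
                plots_dir / f"{slug}_peaks.csv", index=False
            )
        _stage(log, stage, n_plots=len(cut_plots))

        stage = "merge"
        merge_inputs = list(cut_plots)
        for name, h, c in config.singletons:
            merge_inputs.append(
                correlation.singleton_plot(matrix.grid, name, h, c)
            )
        if merge_inputs:
            merged = correlation.merge_plots(merge_inputs)
            bruker_io.write_bruker_processed(
                merged.spectrum, out / "merged", value_scale=1e6
            )
            merged.provenance.to_csv(out / "merged_provenance.csv", index=False)
            _stage(log, stage, n_plots=len(merge_inputs))

        stage = "score"
        references = None
        if config.reference_csv is not None:
            references = {
                r.metabolite: r
                for r in identify.load_reference_peak_lists(config.reference_csv)
            }
        elif ground_truth_refs is not None:
            references = ground_truth_refs
        if references is not None:
            reports = []
            for req, plot in zip(config.peaks, cut_plots):
                if req.metabolite not in references:
                    continue
                reports.append(
                    identify.match_to_reference(
                        identify.extract_plot_peaks(plot),
                        references[req.metabolite],
                        tolerances=config.tolerances,
                        selected_peak=(req.ppm_h, req.ppm_c),
                        cutoff=req.cutoff,
                    )
                )
            identify.reports_to_frame(reports).to_csv(
                out / "recovery.csv", index=False
            )
            _stage(log, stage, n_scored=len(reports))
    except HsqcStocsyError as err:
        raise HsqcStocsyError(f"pipeline failed at stage '{stage}': {err}") from err

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "versions": {
            "hsqcstocsy": _version(),
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "stages": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _version() -> str:
    from . import __version__

    return __version__


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
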