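"""End-to-end orchestration: simulate/load -> segment -> encode -> train
-> evaluate, as one reproducible, configured run.

All randomness flows from ``RunConfig.seed``, fanned out deterministically
to the simulator, the train/test split, class rebalancing and model
training, so a repeated run with the same config on a single CPU thread
produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cnn, encode, evaluate, segment as seg
from .io import CohortManifest, load_cohort
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("acti2img")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run's master seed."""
    stages = ("simulate", "split", "balance", "model")
    if stage not in stages:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), stages.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one full experiment."""

    simulation: SimulationConfig | None = None
    cohort_path: str | None = None
    cohort_layout: str = "depresjon_like"
    windows: tuple[int, ...] = (180,)
    encoder: str = "mtf"
    q: int = 8
    orientation: str = "destination"
    binning_scope: str = "recording"  # or "segment"; MTF quantile edges
    image_size: int = 64
    rp_threshold: float | None = None
    max_gap_fraction: float = 0.1
    align: str = "start"
    model: cnn.ModelConfig = field(default_factory=cnn.ModelConfig)
    split_mode: str = "segment_level"
    test_fraction: float = 0.2
    balance: str = "undersample"  # or "none"
    seed: int = 42
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.cohort_path is None:
            self.simulation = SimulationConfig()
        if not self.windows:
            raise ValueError("windows must be non-empty")
        if self.balance not in ("undersample", "none"):
            raise ValueError("balance must be 'undersample' or 'none'")
        if self.binning_scope not in ("recording", "segment"):
            raise ValueError("binning_scope must be 'recording' or 'segment'")


@dataclass
class ExperimentResult:
    """Everything one run produced, plus a JSON-ready manifest of counts."""

    report: evaluate.EvalReport
    train_report: cnn.TrainReport
    manifest: dict

    def report_json(self) -> str:
        payload = {"report": self.report.as_dict(), "manifest": self.manifest}
        return json.dumps(payload, indent=2, sort_keys=True)


def _get_cohort(config: RunConfig) -> CohortManifest:
    if config.cohort_path is not None:
        return load_cohort(config.cohort_path, layout=config.cohort_layout)
    sim = dataclasses.replace(
        config.simulation, seed=stage_seed(config.seed, "simulate")
    )
    return simulate_cohort(sim)


def _encode_all(
    segments: list[seg.Segment],
    config: RunConfig,
    binnings: dict | None = None,
) -> np.ndarray:
    binnings = binnings or {}
    images = [
        encode.encode_segment(
            s,
            encoder=config.encoder,
            q=config.q,
            orientation=config.orientation,
            size=config.image_size,
            rp_threshold=config.rp_threshold,
            binning=binnings.get(s.participant_id),
        )
        for s in segments
    ]
    return encode.images_to_array(images)


def _recording_binnings(cohort: CohortManifest, config: RunConfig) -> dict:
    """Per-recording quantile edges for MTF, when so configured."""
    if config.encoder != "mtf" or config.binning_scope != "recording":
        return {}
    return {
        rec.participant_id: encode.fit_quantile_bins(rec.counts, config.q)
        for rec in cohort.recordings
    }


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute the full pipeline for one configuration.

    Writes ``report.json``, ``model.npz`` (+ config sidecar) and a stage
    manifest under ``config.output_dir`` when set.  Any stage failure is
    re-raised with the stage name; the partial manifest is persisted if an
    output directory was configured.
    """
    manifest: dict = {"config": _config_dict(config)}
    stage = "load"
    try:
        cohort = _get_cohort(config)
        manifest["participants"] = cohort.group_counts()

        stage = "segment"
        per_window: dict[str, int] = {}
        segments: list[seg.Segment] = []
        for window in config.windows:
            chunk = []
            for rec in cohort.recordings:
                chunk.extend(
                    seg.segment_recording(
                        rec,
                        window,
                        max_gap_fraction=config.max_gap_fraction,
                        align=config.align,
                    )
                )
            per_window[str(window)] = len(chunk)
            segments.extend(chunk)
        manifest["segments_per_window"] = per_window
        manifest["n_segments"] = len(segments)

        stage = "split"
        train_seg, test_seg = evaluate.split_dataset(
            segments,
            mode=config.split_mode,
            test_fraction=config.test_fraction,
            seed=stage_seed(config.seed, "split"),
        )
        manifest["n_train_segments"] = len(train_seg)
        manifest["n_test_segments"] = len(test_seg)

        stage = "balance"
        y_train = np.array([s.label for s in train_seg])
        if config.balance == "undersample":
            keep = cnn.undersample_indices(
                y_train, stage_seed(config.seed, "balance")
            )
            train_seg = [train_seg[i] for i in keep]
            y_train = y_train[keep]
        manifest["n_train_after_balance"] = len(train_seg)

        stage = "encode"
        binnings = _recording_binnings(cohort, config)
        x_train = _encode_all(train_seg, config, binnings)
        x_test = _encode_all(test_seg, config, binnings)
        y_test = np.array([s.label for s in test_seg])
        manifest["n_images"] = int(x_train.shape[0] + x_test.shape[0])

        stage = "train"
        model_config = dataclasses.replace(
            config.model,
            input_size=config.image_size,
            seed=stage_seed(config.seed, "model"),
        )
        model = cnn.build_model(model_config)
        train_report = cnn.train(
            model, x_train, y_train, model_config, validation=(x_test, y_test)
        )

        stage = "evaluate"
        probs = cnn.predict(model, x_test)
        conf = evaluate.confusion(y_test, (probs >= 0.5).astype(int))
        report = evaluate.metrics(
            conf,
            split={
                "mode": config.split_mode,
                "test_fraction": config.test_fraction,
                "seed": config.seed,
                "encoder": config.encoder,
                "windows": list(config.windows),
            },
        )
        if config.split_mode == "segment_level":
            report.flags.append(
                "segment_level split: windows from one participant may appear "
                "in both train and test (optimistic; see participant_level)"
            )
    except Exception as exc:
        manifest["failed_stage"] = stage
        _persist_partial(config, manifest)
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    result = ExperimentResult(
        report=report, train_report=train_report, manifest=manifest
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(result.report_json())
        cnn.save_model(model, out / "model.npz")
        logger.info("artifacts written to %s", out)
    return result


def _persist_partial(config: RunConfig, manifest: dict) -> None:
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "partial_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str)
        )


def _config_dict(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return clean(config)


def compare_encoders(
    config: RunConfig, encoders: list[str]
) -> "list[tuple[str, evaluate.EvalReport]]":
    """Run the pipeline once per encoder on identical cohorts and splits.

    The same master seed is reused for every encoder, so the simulated
    cohort, the segmentation and the split are identical across rows; only
    the image encoding (and hence training inputs) changes.
    """
    if len(encoders) < 2:
        raise ValueError("need at least 2 encoders to compare")
    rows = []
    for enc_name in encoders:
        cfg = dataclasses.replace(config, encoder=enc_name, output_dir=None)
        result = run_experiment(cfg)
        rows.append((enc_name, result.report))
    return rows


def comparison_markdown(rows: "list[tuple[str, evaluate.EvalReport]]") -> str:
    lines = [
        "| Encoder | Accuracy | Precision | Recall | F1-score |",
        "|---|---|---|---|---|",
    ]
    lines += [report.markdown_row(name) for name, report in rows]
    return "\n".join(lines)
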