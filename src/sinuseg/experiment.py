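"""End-to-end workflows: train the two-stage model on phantoms and
evaluate it against ground truth.

These functions are the programmatic equivalent of the CLI commands and
are what the reproduction script drives. All randomness flows from one
seed through a fixed derivation, so a (seed, config) pair identifies a
run completely.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .config import derive_seeds
from .metrics import MetricsReport, evaluate_pair
from .phantoms import PhantomSample
from .pipeline import PipelineConfig, run_pipeline
from .training import TrainConfig, TrainHistory, make_coarse_and_fine_training_pairs, train
from .unet3d import NetworkSpec, UNet3D, build_network

__all__ = ["TwoStageModel", "train_two_stage", "evaluate_model"]


@dataclass
class TwoStageModel:
    coarse: UNet3D
    fine: UNet3D
    coarse_history: TrainHistory
    fine_history: TrainHistory


def train_two_stage(
    train_samples: list[PhantomSample],
    val_samples: list[PhantomSample],
    net_spec: NetworkSpec | None = None,
    train_cfg: TrainConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
    patches_per_sample: int = 2,
    seed: int = 0,
    fine_cfg: TrainConfig | None = None,
    bg_patches_per_sample: float = 0.0,
    fine_net_spec: NetworkSpec | None = None,
) -> TwoStageModel:
    """Train the coarse (fixed-size, whole-volume) and fine (patch) networks.

    The two networks share the architecture spec but get independent
    weights and independent training streams, all derived from ``seed``.
    ``train_cfg`` drives the coarse stage; ``fine_cfg`` (defaulting to
    ``train_cfg``) the fine stage — the two stages have different error
    economics (the proposal stage wants recall, the refinement stage wants
    a calibrated boundary), so their loss weighting may differ.
    """
    net_spec = net_spec or NetworkSpec()
    train_cfg = train_cfg or TrainConfig()
    fine_cfg = fine_cfg or train_cfg
    pipe_cfg = pipe_cfg or PipelineConfig()
    s = derive_seeds(seed, 6)
    coarse_train, fine_train = make_coarse_and_fine_training_pairs(
        train_samples, pipe_cfg.coarse_fixed_size, pipe_cfg.patch_size,
        patches_per_sample=patches_per_sample, seed=s[0],
        bg_patches_per_sample=bg_patches_per_sample,
    )
    coarse_val, fine_val = make_coarse_and_fine_training_pairs(
        val_samples, pipe_cfg.coarse_fixed_size, pipe_cfg.patch_size,
        patches_per_sample=patches_per_sample, seed=s[1],
        bg_patches_per_sample=bg_patches_per_sample,
    )
    coarse_net = build_network(net_spec, seed=s[2])
    fine_net = build_network(fine_net_spec or net_spec, seed=s[3])
    _, hist_c = train(coarse_net, coarse_train, coarse_val, dataclasses.replace(train_cfg, seed=s[4]))
    _, hist_f = train(fine_net, fine_train, fine_val, dataclasses.replace(fine_cfg, seed=s[5]))
    return TwoStageModel(coarse_net, fine_net, hist_c, hist_f)


def evaluate_model(
    model: TwoStageModel,
    samples: list[PhantomSample],
    pipe_cfg: PipelineConfig | None = None,
    with_meshes: bool = False,
) -> list[MetricsReport]:
    """Run the full pipeline on each sample and score it against truth."""
    pipe_cfg = pipe_cfg or PipelineConfig()
    reports = []
    for sample in samples:
        res = run_pipeline(sample.volume, model.coarse, model.fine, pipe_cfg,
                           extract_surface=with_meshes)
        reports.append(evaluate_pair(res.mask, sample.truth))
    return reports
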