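"""Shared study-condition presets.

``desk_protocol`` is the package's standard small-scale experimental
condition: a 40-task synthetic family with heterogeneous task sizes, tiny
learner widths, and a short meta-training schedule (5 outer epochs x 20
meta-updates, candidate pool B=8, N_slct=4, first-order meta-gradients).
It exists so tests, examples and the reproduction script all run the same
conditions rather than each inventing their own.
"""

from __future__ import annotations

from dataclasses import replace

from .base_learner import LearnerConfig
from .meta_engine import MetaTrainConfig, NoiseConfig
from .synthetic import SyntheticConfig

__all__ = ["desk_protocol"]


def desk_protocol(seed: int = 0, noisy_task_fraction: float = 0.2):
    """(SyntheticConfig, LearnerConfig, MetaTrainConfig, NoiseConfig) tuple."""
    syn = SyntheticConfig(
        n_tasks=40,
        records_per_task=(12, 24),
        molecule_size=(6, 12),
        protein_length=(30, 60),
        noisy_task_fraction=noisy_task_fraction,
        seed=seed,
    )
    learner = LearnerConfig.tiny("GCN", inner_lr=0.01, outer_lr=0.01)
    train = MetaTrainConfig(
        epochs=5,
        updates_per_epoch=20,
        batch_candidates=8,
        n_select=4,
        support_size=5,
        mode="first_order",
        val_batch=2,
        adapter_lr=1.0,
    )
    return syn, learner, train, NoiseConfig(sigma=0.1)
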