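"""Network transfer: student training with the hidden-vector matching
penalty against a frozen teacher.

The objective per batch is mean cross-entropy plus ``lambda * ||H_S - H_L||^2``
averaged over the batch, where both hidden vectors come from the SAME
augmented view of each image. The teacher runs in evaluation mode and its
parameters are asserted unchanged at the end of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .imaging import AugmentationConfig
from .network import ModelState
from .synthetic import LabeledDataset
from .training import TraceRow, TrainConfig, run_sgd

__all__ = ["TransferConfig", "transfer_train"]


@dataclass(frozen=True)
class TransferConfig:
    lambda_: float = 1.0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("transfer weight lambda must be non-negative")


def _fingerprint(model: ModelState):
    return [(i, k, v.tobytes()) for i, p in enumerate(model.params)
            for k, v in sorted(p.items())]


def transfer_train(student: ModelState, teacher: ModelState,
                   data: LabeledDataset, aug: AugmentationConfig,
                   cfg: TransferConfig, log=None) -> Tuple[ModelState, List[TraceRow]]:
    """Train the student under the combined transfer objective.

    Requires equal teacher/student hidden dimensions (no adapter is enabled
    by default; a dimension mismatch fails fast). With ``lambda_=0`` the
    parameter trajectory is identical to plain cross-entropy training under
    the same seed and schedule.
    """
    if teacher.spec.hidden_dim != student.spec.hidden_dim:
        raise ValueError(
            f"teacher hidden dim {teacher.spec.hidden_dim} != student "
            f"{student.spec.hidden_dim}; enable an adapter or match the specs")
    before = _fingerprint(teacher)
    student, trace = run_sgd(student, data, aug, cfg.train,
                             teacher=teacher, penalty_weight=cfg.lambda_, log=log)
    after = _fingerprint(teacher)
    assert before == after, "frozen teacher was mutated during transfer"
    return student, trace
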