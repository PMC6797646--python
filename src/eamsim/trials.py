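"""Shared container for simulated decision trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialSet"]


@dataclass
class TrialSet:
    """Outcome of a batch of simulated trials.

    ``resp`` codes the chosen alternative (1-based); 0 marks a trial that
    never reached threshold within the step budget, in which case ``rt`` is
    NaN.  Simulators guarantee rt > non-decision time for terminated trials.
    """

    resp: np.ndarray
    rt: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.resp = np.asarray(self.resp, dtype=np.int64)
        self.rt = np.asarray(self.rt, dtype=np.float64)
        if self.resp.shape != self.rt.shape:
            raise ValueError(
                f"resp and rt must have equal length; got {self.resp.shape} vs {self.rt.shape}"
            )

    def __len__(self) -> int:
        return self.resp.shape[0]

    @property
    def n_nonterminated(self) -> int:
        return int(np.count_nonzero(self.resp == 0))

    def terminated(self) -> "TrialSet":
        keep = self.resp > 0
        return TrialSet(self.resp[keep], self.rt[keep])

    def signed_rt(self) -> np.ndarray:
        """Terminated RTs with alternative-2 responses negated.

        The signed pooling summarizes choices and RTs in a single
        one-dimensional sample, mirroring the convention of plotting
        second-alternative RTs on the negative axis.
        """
        t = self.terminated()
        return np.where(t.resp == 2, -t.rt, t.rt)
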