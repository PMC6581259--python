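"""Model-style facade over the full pipeline.

``HierarchicalBCI`` is constructed from data (an epoch set, a session, a
file or a simulation preset) plus a configuration; ``fit()`` executes the
5-run protocol and returns the :class:`~bcihier.evaluation.EvaluationReport`
results object with the point estimates, their run-to-run dispersion, the
confusion-matrix diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from .config import PipelineConfig
from .evaluation import EvaluationReport
from .io import EpochSet, RawSession, load_session
from .pipeline import (evaluate_hierarchical, one_level_baseline,
                       session_epochs, two_level_supervised_baseline)
from .simulate import make_subject_suite


class HierarchicalBCI:
    """Two-level reject-then-classify BCI model bound to one subject's data.

    Parameters
    ----------
    epochs : EpochSet
        Labelled IC/NC epochs (already prefiltered).
    config : PipelineConfig, optional
        Every pipeline tunable; defaults reproduce the published operating
        point (K=35, IC threshold 80%, 5 projections, 3 sub-bands).

    Examples
    --------
    >>> from bcihier import HierarchicalBCI
    >>> model = HierarchicalBCI.from_simulation("expert", seed=7,
    ...                                         n_channels=16,
    ...                                         n_trials_per_class=24)
    >>> res = model.fit(select_grid=True)
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, epochs: EpochSet, config: PipelineConfig = None,
                 subject_id: str = ""):
        self.epochs = epochs
        self.config = config or PipelineConfig()
        self.subject_id = subject_id

    @classmethod
    def from_session(cls, session: RawSession,
                     config: PipelineConfig = None) -> "HierarchicalBCI":
        """Prefilter a raw session and cut epochs per the trial template."""
        config = config or PipelineConfig()
        return cls(session_epochs(session, config), config,
                   subject_id=session.subject_id)

    @classmethod
    def from_file(cls, path, config: PipelineConfig = None,
                  fmt: str = None) -> "HierarchicalBCI":
        return cls.from_session(load_session(path, fmt=fmt), config)

    @classmethod
    def from_simulation(cls, skill: str = "expert", seed: int = 0,
                        config: PipelineConfig = None,
                        **sim_kwargs) -> "HierarchicalBCI":
        session, _ = make_subject_suite(skill, seed=seed, **sim_kwargs)
        model = cls.from_session(session, config)
        model.subject_id = f"sim-{skill}"
        return model

    def fit(self, seed: int = None,
            select_grid: bool = False) -> EvaluationReport:
        """Run the 5-run protocol; returns the results object."""
        return evaluate_hierarchical(self.epochs, self.config, seed=seed,
                                     select_grid=select_grid,
                                     subject_id=self.subject_id)

    def fit_baseline(self, kind: str = "one-level", seed: int = None,
                     **kwargs) -> EvaluationReport:
        """Supervised baselines under the same protocol.

        ``kind`` is "one-level" (single 5-class classifier) or "two-level"
        (supervised IC/NC gate + 4-class classifier).
        """
        if kind == "one-level":
            rep = one_level_baseline(self.epochs, config=self.config,
                                     seed=seed, subject_id=self.subject_id,
                                     **kwargs)
        elif kind == "two-level":
            rep = two_level_supervised_baseline(
                self.epochs, config=self.config, seed=seed,
                subject_id=self.subject_id, **kwargs)
        else:
            raise ValueError("kind must be 'one-level' or 'two-level'")
        return rep
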