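"""Filter bookkeeping shared by the count and array pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FilterReport:
    """Record of one feature-filtering stage.

    Stages compose: the ``features_out`` of one stage is the
    ``features_in`` of the next, so a chain of reports telescopes from
    the raw feature count down to the final tested set.
    """

    stage: str
    features_in: int
    features_removed: int
    rule: str = ""

    def __post_init__(self) -> None:
        if self.features_removed > self.features_in:
            raise ValueError("removed more features than were present")

    @property
    def features_out(self) -> int:
        return self.features_in - self.features_removed


@dataclass
class FilterChain:
    """Ordered sequence of :class:`FilterReport` stages."""

    reports: list[FilterReport] = field(default_factory=list)

    def add(self, stage: str, features_in: int, features_removed: int, rule: str = "") -> FilterReport:
        rep = FilterReport(stage, features_in, features_removed, rule)
        if self.reports and self.reports[-1].features_out != features_in:
            raise ValueError(
                f"stage '{stage}' starts from {features_in} features but the "
                f"previous stage left {self.reports[-1].features_out}"
            )
        self.reports.append(rep)
        return rep

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "stage": r.stage,
                    "features_in": r.features_in,
                    "features_removed": r.features_removed,
                    "features_out": r.features_out,
                    "rule": r.rule,
                }
                for r in self.reports
            ]
        )
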