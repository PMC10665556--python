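"""Result records shared by every analysis arm."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GroupComparison:
    """One pairwise group test: estimate, raw p, FDR-adjusted p, labels.

    All arms (methylation, tetramer frequencies, aligned-cluster
    proportions, serology models) report their pairwise tests in this
    shape so result tables can be concatenated and post-processed
    uniformly.

    Attributes
    ----------
    comparison:
        Label of the group pair, e.g. ``"at_risk_vs_ctrl"``.
    outcome:
        Name of the quantity tested (probe, antigen group, aligned
        cluster, ...).
    estimate:
        Test-specific effect estimate (difference of means, model
        coefficient, rank-sum statistic, ...).
    p:
        Two-sided raw p-value; ``nan`` when the test is degenerate.
    p_adj:
        FDR-adjusted p-value; ``nan`` until adjustment is applied
        across the relevant family.
    method:
        Short name of the statistical test used.
    flags:
        Free-form quality flags ("degenerate", "separation", ...).
    """

    comparison: str
    outcome: str
    estimate: float
    p: float
    p_adj: float = float("nan")
    method: str = ""
    flags: list[str] = field(default_factory=list)


GROUPS = ("ctrl", "at_risk", "early_ra")
#: The two pairwise contrasts reported throughout: the at-risk state vs
#: seronegative controls, and at-risk vs early clinical disease.
DEFAULT_PAIRS = (("ctrl", "at_risk"), ("at_risk", "early_ra"))
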