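"""Ordered-pair edge scores and two-direction averaging."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["EdgeScoreTable", "average_directions"]


@dataclass
class EdgeScoreTable:
    """Posterior inclusion scores per ordered (response, feature) pair.

    ``scores[(a, b)]`` is the model-averaged inclusion probability of feature
    ``b`` in the regression with response ``a``. ``roles`` maps node id to
    'expression' | 'genotype' | 'phenotype'. Genotype nodes never appear as
    responses.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    def add(self, response: str, feature: str, score: float) -> None:
        if self.roles.get(response) == "genotype":
            raise ValueError(f"genotype node {response!r} cannot be a response")
        if response == feature:
            raise ValueError(f"self-pair {response!r}")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        self.scores[(response, feature)] = float(score)

    def update_from(self, other: "EdgeScoreTable") -> None:
        self.scores.update(other.scores)
        self.roles.update(other.roles)

    def symmetric(self) -> dict[frozenset, float]:
        """Direction-averaged scores; single-direction pairs pass through."""
        out: dict[frozenset, float] = {}
        done = set()
        for (a, b), s in self.scores.items():
            key = frozenset((a, b))
            if key in done:
                continue
            rev = self.scores.get((b, a))
            out[key] = s if rev is None else 0.5 * (s + rev)
            done.add(key)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "response": a,
                "feature": b,
                "role_response": self.roles.get(a, ""),
                "role_feature": self.roles.get(b, ""),
                "p_hat": s,
            }
            for (a, b), s in sorted(self.scores.items())
        ]
        return pd.DataFrame(
            rows, columns=["response", "feature", "role_response", "role_feature", "p_hat"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EdgeScoreTable":
        t = cls()
        for row in df.itertuples(index=False):
            t.roles.setdefault(row.response, row.role_response)
            t.roles.setdefault(row.feature, row.role_feature)
            t.add(row.response, row.feature, row.p_hat)
        return t


def average_directions(scores: EdgeScoreTable) -> EdgeScoreTable:
    """Return a table holding the symmetric (direction-averaged) scores.

    Pairs scored in both directions receive the arithmetic mean; pairs scored
    in one direction only (phenotype-feature, anything-genotype) pass through
    unchanged. Both orderings of averaged pairs are stored so downstream
    lookups are order-free.
    """
    out = EdgeScoreTable(roles=dict(scores.roles))
    for key, s in scores.symmetric().items():
        a, b = sorted(key)
        out.scores[(a, b)] = s
    return out
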