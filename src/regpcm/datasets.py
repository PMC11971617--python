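"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .patterns import PatternCounts, TestDesign, load_pattern_counts

__all__ = ["load_aggression", "AGGRESSION_DESIGN"]

#: Five items, five ordered categories each (scores 0-4).
AGGRESSION_DESIGN = TestDesign(m=(4, 4, 4, 4, 4))


def load_aggression() -> PatternCounts:
    """Aggressive antisocial behaviour questionnaire data.

    Responses of 493 adolescents to five items asking how often each
    antisocial act was committed in the last 12 months (0 = never up to
    4 = more than ten times), collapsed to 85 distinct score patterns
    with frequencies.  The bundled table also carries a two-part random
    pattern partition (labels 1/2) used by the split-sample fit test.
    """
    with resources.as_file(
        resources.files("regpcm") / "data" / "aggression_patterns.csv"
    ) as path:
        return load_pattern_counts(path, AGGRESSION_DESIGN)
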