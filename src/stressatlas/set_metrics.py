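"""Set-overlap metrics comparing single- and combined-stress DEG responses.

For a combined condition ``xy`` with single-stress DEG sets Sx, Sy (first and
second letter of the code) and combined set Sxy, three metrics summarize the
interaction, per direction:

* ``similarity``  — Jaccard index of Sx and Sy: do the two single stresses
  elicit the same genes?
* ``suppression`` — fraction of Sx lost in the combination minus fraction of
  Sy lost: +1 means the combined response kept Sy and dropped Sx (Sy
  suppresses Sx), -1 the reverse, 0 means nothing was lost asymmetrically.
* ``novelty``     — fraction of Sxy found in neither single stress: 1 means
  the combination elicited an entirely new response.

Empty-set conventions: every undefined ratio contributes 0, so all range
invariants hold degenerately.
"""

from __future__ import annotations

import pandas as pd

from .degs import DEGSets


def similarity(sx: set, sy: set) -> float:
    union = sx | sy
    if not union:
        return 0.0
    return len(sx & sy) / len(union)


def suppression(sx: set, sy: set, sxy: set) -> float:
    lost_x = len(sx - sxy) / len(sx) if sx else 0.0
    lost_y = len(sy - sxy) / len(sy) if sy else 0.0
    return lost_x - lost_y


def novelty(sx: set, sy: set, sxy: set) -> float:
    if not sxy:
        return 0.0
    return len(sxy - (sx | sy)) / len(sxy)


def pair_metrics(sx: set, sy: set, sxy: set) -> dict[str, float]:
    return {
        "similarity": similarity(sx, sy),
        "suppression": suppression(sx, sy, sxy),
        "novelty": novelty(sx, sy, sxy),
    }


def all_pair_metrics(degsets: DEGSets, combined_codes) -> pd.DataFrame:
    """Metrics for every combined condition and direction (18 x 2 rows)."""
    rows = []
    for code in combined_codes:
        x, y = code[0], code[1]
        for cond in (x, y, code):
            if cond not in degsets:
                raise KeyError(f"missing DEG sets for condition {cond!r}")
        for direction in ("up", "down"):
            sx = degsets[x][direction]
            sy = degsets[y][direction]
            sxy = degsets[code][direction]
            rows.append(
                {"combo": code, "direction": direction, **pair_metrics(sx, sy, sxy)}
            )
    return pd.DataFrame(rows)
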