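"""Single-HSC transplantation analytics.

Clones are included when any lineage reaches 0.1% contribution at some
analysed time point; lineage bias is called by the threefold-output rule at
both 10 and 16 weeks (platelet-biased Pl, platelet/myeloid Pl/My,
lymphoid-biased Ly, balanced Ba); platelet-restricted clones show platelet
output with no detectable myeloid, B or T output. Subtype frequencies
between groups are compared by Fisher's exact test, reconstitution levels
by Mann–Whitney, and repopulation frequency is estimated from a limiting
dilution under the single-hit Poisson model
f = -ln((n - k) / n) / dose.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .datatypes import CloneRecord
from .diffexp import fisher_exact_2x2, wilcoxon_level_test

BIAS_LABELS = ("Pl", "Pl/My", "Ba", "Ly")


@dataclass
class BiasCall:
    clone_id: str
    label: str
    platelet_restricted: bool
    basis: dict[int, dict[str, float]]


@dataclass
class LdaEstimate:
    dose: float
    n: int
    k: int
    frequency: float

    @property
    def percent(self) -> float:
        return 100.0 * self.frequency


def filter_clones(
    clones: list[CloneRecord], min_contrib: float = 0.1
) -> list[CloneRecord]:
    """Clones with >= min_contrib percent in some lineage at some time point."""
    return [
        c
        for c in clones
        if any(
            v >= min_contrib for lin in c.contributions.values() for v in lin.values()
        )
    ]


def mean_contribution(clone: CloneRecord, week: int) -> float:
    """Average of the four lineage contributions at one time point."""
    if week not in clone.contributions:
        raise ValueError(f"clone {clone.clone_id}: no week {week}")
    lin = clone.contributions[week]
    return (lin["platelet"] + lin["myeloid"] + lin["B"] + lin["T"]) / 4.0


def _label_at_week(
    lin: dict[str, float], ratio: float, lymphoid: str
) -> str:
    p, m = lin["platelet"], lin["myeloid"]
    if lymphoid == "max":
        l = max(lin["B"], lin["T"])
    elif lymphoid == "sum":
        l = lin["B"] + lin["T"]
    else:
        raise ValueError(f"unknown lymphoid mode {lymphoid!r}")
    if p >= ratio * m and p >= ratio * l:
        return "Pl"
    if min(p, m) >= ratio * l:
        return "Pl/My"
    if l >= ratio * m and l >= ratio * p:
        return "Ly"
    return "Ba"


def classify_bias(
    clone: CloneRecord,
    weeks: tuple[int, ...] = (10, 16),
    ratio: float = 3.0,
    lymphoid: str = "max",
    detect_floor: float = 0.01,
) -> BiasCall:
    """Threefold-rule lineage-bias call, required to hold at every analysed week.

    With P = platelet, M = myeloid and L the lymphoid summary (max of B and
    T by default): Pl if P >= r*M and P >= r*L; else Pl/My if min(P, M) >=
    r*L; else Ly if L >= r*M and L >= r*P; else Ba. Discordant weeks yield
    Ba. The platelet-restricted flag additionally requires the Pl label.
    """
    present = [w for w in weeks if w in clone.contributions]
    if not present:
        raise ValueError(
            f"clone {clone.clone_id}: none of the analysed weeks {weeks} present"
        )
    labels = {_label_at_week(clone.contributions[w], ratio, lymphoid) for w in present}
    label = labels.pop() if len(labels) == 1 else "Ba"
    restricted = label == "Pl" and platelet_restricted(
        clone, weeks=tuple(present), detect_floor=detect_floor
    )
    return BiasCall(
        clone_id=clone.clone_id,
        label=label,
        platelet_restricted=restricted,
        basis={w: dict(clone.contributions[w]) for w in present},
    )


def platelet_restricted(
    clone: CloneRecord,
    weeks: tuple[int, ...] = (10, 16),
    detect_floor: float = 0.01,
    min_platelet: float = 0.1,
) -> bool:
    """Platelet output detected with no other lineage ever above the floor."""
    present = [w for w in weeks if w in clone.contributions]
    if not present:
        return False
    platelet_ok = any(
        clone.contributions[w]["platelet"] >= min_platelet for w in present
    )
    others_silent = all(
        clone.contributions[w][l] < detect_floor
        for w in present
        for l in ("myeloid", "B", "T")
    )
    return platelet_ok and others_silent


def subtype_frequency_test(
    counts_a: dict[str, int], counts_b: dict[str, int]
) -> dict[str, float]:
    """Per-label Fisher exact p for label-vs-rest x group 2x2 tables."""
    total_a, total_b = sum(counts_a.values()), sum(counts_b.values())
    out = {}
    for label in sorted(set(counts_a) | set(counts_b)):
        ka, kb = counts_a.get(label, 0), counts_b.get(label, 0)
        out[label] = fisher_exact_2x2(ka, total_a - ka, kb, total_b - kb)
    return out


def subtype_counts(calls: list[BiasCall]) -> dict[str, int]:
    return dict(Counter(c.label for c in calls))


def reconstitution_comparison(values_a, values_b) -> float:
    """Two-sided Mann–Whitney p comparing clone reconstitution levels."""
    return wilcoxon_level_test(values_a, values_b)


def poisson_lda(n: int, k: int, dose: float) -> LdaEstimate:
    """Single-hit Poisson limiting-dilution frequency per transplanted cell.

    With k of n recipients reconstituted at ``dose`` cells each, the
    fraction of negative recipients estimates exp(-f * dose), giving
    f = -ln((n - k) / n) / dose. All recipients positive leaves no finite
    estimate and is an error.
    """
    if n <= 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n with n > 0, got n={n}, k={k}")
    if dose < 1:
        raise ValueError(f"dose must be >= 1, got {dose}")
    if k == n:
        raise ValueError("all recipients reconstituted: frequency unbounded")
    return LdaEstimate(dose=dose, n=n, k=k, frequency=-math.log((n - k) / n) / dose)
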