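"""Published screen catalog: receptor categories and pair counts.

Reference lists for the mouse odorant-receptor screen this package's
analysis was designed around: 24 receptors tested against 28 odorants,
51 receptor-ligand pairs in total. Receptors split into Category 1
(RTP1S-dominated, RTP2 suppressive; 34 pairs over 22 odorants) and
Category 2 (enhanced by both chaperones; 17 pairs over 16 odorants).
Counts are derived from the name lists at call time rather than stored.
"""

from __future__ import annotations

CATEGORY1_RECEPTORS: tuple[str, ...] = (
    "MOR106-1",
    "MOR139-1",
    "MOR143-2",
    "MOR162-1",
    "MOR180-1",
    "MOR185-1",
    "MOR203-1",
    "MOR244-3",
    "MOR256-3",
    "MOR258-1",
    "MOR258-5",
    "MOR267-13",
    "MOR277-1",
    "MOR30-1",
    "MOR32-4",
    "MOR40-1",
    "MOR41-1",
    "MOR42-3",
)

CATEGORY2_RECEPTORS: tuple[str, ...] = (
    "MOR174-9",
    "MOR23-1",
    "MOR256-17",
    "MOR259-1",
    "MOR261-1",
    "MOR271-1",
)

#: receptor-ligand pair counts per category (the per-pair mapping itself is
#: not published as a table)
PAIR_COUNTS = {"category1": 34, "category2": 17}

N_ODORANTS_SCREENED = 28
N_ODORANTS_BY_CATEGORY = {"category1": 22, "category2": 16}


def screen_summary() -> dict:
    """Headline counts of the reference screen, computed from the lists."""
    overlap = set(CATEGORY1_RECEPTORS) & set(CATEGORY2_RECEPTORS)
    if overlap:
        raise AssertionError(f"catalog categories overlap: {overlap}")
    return {
        "n_category1_receptors": len(CATEGORY1_RECEPTORS),
        "n_category2_receptors": len(CATEGORY2_RECEPTORS),
        "n_receptors": len(CATEGORY1_RECEPTORS) + len(CATEGORY2_RECEPTORS),
        "n_odorants": N_ODORANTS_SCREENED,
        "n_pairs_category1": PAIR_COUNTS["category1"],
        "n_pairs_category2": PAIR_COUNTS["category2"],
        "n_pairs": PAIR_COUNTS["category1"] + PAIR_COUNTS["category2"],
    }
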