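"""Positional scheme of the 20 homologous setal groups on a biramous trunk limb.

A fully developed trunk limb of *Speleonectes tulumensis* carries its setae
and spines in 20 positionally fixed groups: groups 1-8 on the 3-segmented
exopod and groups 9-20 on the 4-segmented endopod. The scheme maps each
group onto its ramus and ramal segment, which is what allows per-segment
setal sums and segment-presence inference from missing column blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EXOPOD = "exopod"
ENDOPOD = "endopod"

#: groups whose elements are short rigid spines rather than flexible setae
SPINE_GROUPS = frozenset({2, 4, 5, 12, 13, 16, 17})

#: (ramus, segment name, group ids) in proximal-to-distal anatomical order
SEGMENT_BLOCKS: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    (EXOPOD, "proximal", (1, 2)),
    (EXOPOD, "middle", (3, 4, 5, 6)),
    (EXOPOD, "distal", (7, 8)),
    (ENDOPOD, "proximal", (9, 10)),
    (ENDOPOD, "mid-proximal", (11, 12, 13, 14)),
    (ENDOPOD, "mid-distal", (15, 16, 17, 18)),
    (ENDOPOD, "distal", (19, 20)),
)


@dataclass(frozen=True)
class SetalGroupScheme:
    """Mapping of setal groups 1-20 onto the seven ramal segments.

    The default instance encodes the canonical arrangement; an alternative
    block layout can be supplied for sensitivity analyses but must still
    partition groups 1-20.
    """

    blocks: tuple[tuple[str, str, tuple[int, ...]], ...] = SEGMENT_BLOCKS
    spine_groups: frozenset[int] = SPINE_GROUPS
    n_groups: int = field(default=20)

    def __post_init__(self) -> None:
        seen: list[int] = []
        for _, _, groups in self.blocks:
            seen.extend(groups)
        if sorted(seen) != list(range(1, self.n_groups + 1)):
            raise ValueError(
                f"segment blocks must partition groups 1..{self.n_groups}, got {sorted(seen)}"
            )

    @property
    def segment_labels(self) -> list[str]:
        """Labels like ``'exopod proximal'`` in anatomical order."""
        return [f"{ramus} {seg}" for ramus, seg, _ in self.blocks]

    def groups_of(self, ramus: str, segment: str) -> tuple[int, ...]:
        for r, s, groups in self.blocks:
            if r == ramus and s == segment:
                return groups
        raise KeyError(f"no segment {segment!r} on {ramus!r}")

    def segment_of(self, group_id: int) -> tuple[str, str]:
        """Return (ramus, segment) of a group id."""
        for ramus, seg, groups in self.blocks:
            if group_id in groups:
                return ramus, seg
        raise KeyError(f"group {group_id} not in scheme")

    def element_kind(self, group_id: int) -> str:
        if not 1 <= group_id <= self.n_groups:
            raise KeyError(f"group {group_id} not in scheme")
        return "spine" if group_id in self.spine_groups else "seta"

    def ramus_blocks(self, ramus: str) -> list[tuple[str, tuple[int, ...]]]:
        return [(seg, groups) for r, seg, groups in self.blocks if r == ramus]


DEFAULT_SCHEME = SetalGroupScheme()
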