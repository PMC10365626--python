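"""Fixed catalogs of chronic-condition groups and frailty deficits.

The analysis never touches raw diagnostic codes: conditions and deficits
enter as precomputed binary flags aligned to an ordered catalog.  The
defaults emulate the shape of the standard instruments used for older
populations — 60 chronic-condition groups for multimorbidity and a
36-deficit cumulative-deficit frailty index (20 disease-related deficits,
16 derived from signs, symptoms, laboratory results, and disabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_codes(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class ConditionCatalog:
    """Ordered catalog of chronic-condition group identifiers."""

    codes: tuple[str, ...] = field(default_factory=lambda: _default_codes("c", 60))

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise ValueError("condition catalog must not be empty")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("condition catalog identifiers must be unique")
        if any(not c for c in self.codes):
            raise ValueError("condition catalog identifiers must be non-empty")

    @property
    def size(self) -> int:
        return len(self.codes)

    def columns(self) -> list[str]:
        """Column names used in the long person-year table."""
        return [f"cond_{c}" for c in self.codes]


@dataclass(frozen=True)
class DeficitCatalog:
    """Ordered catalog of frailty deficits with the disease/SSLD partition.

    ``disease_related[i]`` is True for deficits that are themselves chronic
    diseases, False for signs/symptoms/laboratory/disability deficits.
    """

    codes: tuple[str, ...] = field(default_factory=lambda: _default_codes("d", 36))
    disease_related: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if len(self.codes) == 0:
            raise ValueError("deficit catalog must not be empty")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("deficit catalog identifiers must be unique")
        if not self.disease_related:
            # default partition: first 20 disease-related, rest SSLD
            n_dis = min(20, len(self.codes))
            object.__setattr__(
                self,
                "disease_related",
                tuple(i < n_dis for i in range(len(self.codes))),
            )
        if len(self.disease_related) != len(self.codes):
            raise ValueError("disease_related must cover every deficit")

    @property
    def size(self) -> int:
        return len(self.codes)

    def columns(self) -> list[str]:
        return [f"def_{c}" for c in self.codes]
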