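"""Hierarchical category scheme for phenotype annotation.

The default scheme is the 16-category COPD phenotype scheme: a forest with
four roots (``Problem``, ``Treatment``, ``Test``, ``ConstituentConcept``)
whose leaves distinguish conditions, risk factors, signs/symptoms, test
results, drugs, proteins, anatomical concepts and qualities.  Other disease
schemes can be loaded from the same declarative label/parent file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


class SchemeError(ValueError):
    """A category is unknown, or a scheme file is malformed."""


#: Variant spellings seen in the wild for the COPD scheme, folded onto the
#: canonical label set.
COPD_ALIASES: dict[str, str] = {
    "TestOrMeasureResult": "TestResult",
    "TestOrMesureResult": "TestResult",
    "TestOrMeasure": "Test",
    "MedicalCondition": "Condition",
}


@dataclass(frozen=True)
class SchemeHierarchy:
    """A forest of category labels.

    Parameters
    ----------
    labels
        Every category name in the scheme.
    parent
        Mapping from each non-root label to its parent label.
    aliases
        Optional variant spellings resolved onto canonical labels.
    """

    labels: frozenset[str]
    parent: dict[str, str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if child not in self.labels or par not in self.labels:
                raise SchemeError(f"parent entry {child!r}->{par!r} uses unknown label")
        # acyclicity: walking up from any node must terminate
        for label in self.labels:
            seen = set()
            node = label
            while node in self.parent:
                if node in seen:
                    raise SchemeError(f"cycle in scheme at {node!r}")
                seen.add(node)
                node = self.parent[node]

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(l for l in self.labels if l not in self.parent)

    def canonical(self, label: str) -> str:
        """Resolve *label* (or an alias of it) to its canonical name.

        Raises
        ------
        SchemeError
            If the label is not in the scheme and not a known alias.
        """
        if label in self.labels:
            return label
        if label in self.aliases:
            return self.aliases[label]
        raise SchemeError(f"unknown category {label!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.labels or label in self.aliases

    def ancestors(self, label: str) -> list[str]:
        out = []
        node = self.canonical(label)
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out


def load_scheme(path: str | Path, aliases: dict[str, str] | None = None) -> SchemeHierarchy:
    """Load a scheme from a two-column label/parent TSV file.

    Lines starting with ``#`` are comments; a parent of ``-`` marks a root.
    """
    labels: set[str] = set()
    parent: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemeError(f"{path}:{lineno}: expected 'label<TAB>parent', got {raw!r}")
        label, par = parts
        labels.add(label)
        if par != "-":
            parent[label] = par
    return SchemeHierarchy(frozenset(labels), parent, dict(aliases or {}))


def copd_scheme() -> SchemeHierarchy:
    """The packaged 16-category COPD phenotype scheme."""
    with resources.as_file(resources.files("phenonest.data") / "copd_scheme.tsv") as p:
        return load_scheme(p, aliases=COPD_ALIASES)
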