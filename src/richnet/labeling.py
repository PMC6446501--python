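"""Automatic annotation of gene-set clusters from set-name term frequencies.

Curated set names (e.g. ``REACTOME_SMOOTH_MUSCLE_CONTRACTION``) are
underscore-delimited phrases whose words often repeat across the members of
a cluster. A cluster title is built from the most frequent informative
words: names are tokenized, generic pathway-vocabulary and English stopwords
are excluded, and the top ``top_k`` tokens occurring at least ``min_freq``
times (default: four tokens, frequency >= 2) are joined into a title. A
cluster whose names share no repeated informative word gets an empty title —
often a hint of a semantically mixed cluster.

Per-node display labels are simpler: words 2-5 of the set name (the first
word is usually the library of origin), with trailing PATHWAY / SIGNALING
boilerplate stripped; omitted entirely in clusters of more than five nodes
to avoid overprinting.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, field

__all__ = [
    "ExclusionWordList",
    "ClusterLabel",
    "DEFAULT_EXCLUSION",
    "tokenize",
    "cluster_title",
    "node_display_label",
    "format_title",
]

# domain vocabulary too generic to distinguish clusters
PATHWAY_VOCAB_WORDS = (
    "cell", "process", "regulation", "negative", "positive", "signaling",
    "response", "stimulus", "signal", "activity", "protein", "involved",
    "component", "level", "effector", "event", "projection", "organismal",
    "cellular", "modification", "pathway", "mediated", "dependent",
    "organization", "group", "target", "biocarta", "kegg", "reactome",
)

# compact classic English stopword list, vendored so titles never depend on
# an external corpus package
ENGLISH_STOPWORDS = (
    "a", "about", "an", "and", "are", "as", "at", "be", "by", "for",
    "from", "how", "in", "is", "it", "of", "on", "or", "that", "the",
    "this", "to", "was", "what", "when", "where", "which", "who", "will",
    "with", "via",
)

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)
_NUMBER_RE = re.compile(r"^\d+$")


@dataclass(frozen=True)
class ExclusionWordList:
    """Lowercase words never used in cluster titles."""

    words: frozenset[str] = field(
        default_factory=lambda: frozenset(PATHWAY_VOCAB_WORDS + ENGLISH_STOPWORDS)
    )

    def __post_init__(self) -> None:
        bad = [w for w in self.words if not w or w != w.lower()]
        if bad:
            raise ValueError(f"exclusion words must be lowercase and non-empty: {bad}")

    def __contains__(self, word: str) -> bool:
        return word in self.words


DEFAULT_EXCLUSION = ExclusionWordList()


@dataclass(frozen=True)
class ClusterLabel:
    """Machine-generated title for one cluster plus its term diagnostics."""

    cluster_id: int | None
    title: str
    term_freqs: dict[str, int]


def tokenize(name: str, excl: ExclusionWordList = DEFAULT_EXCLUSION) -> list[str]:
    """Informative lowercase tokens of a gene-set name.

    Split on underscore, lowercase, strip punctuation characters, drop
    tokens that are empty, purely numeric, excluded, or the literal "na".
    """
    tokens = []
    for raw in name.split("_"):
        tok = raw.lower().translate(_PUNCT_TABLE)
        if not tok or _NUMBER_RE.match(tok) or tok == "na" or tok in excl:
            continue
        tokens.append(tok)
    return tokens


def cluster_title(
    names: Iterable[str],
    excl: ExclusionWordList = DEFAULT_EXCLUSION,
    top_k: int = 4,
    min_freq: int = 2,
    cluster_id: int | None = None,
) -> ClusterLabel:
    """Title a cluster by its most frequent informative name tokens.

    Token counts are pooled over all member names; tokens with count >=
    ``min_freq`` qualify; the title joins up to ``top_k`` of them, ordered
    by decreasing count. Ties keep the order in which tokens first appear
    when member names are scanned in sorted order — this mirrors a stable
    decreasing sort of the pooled term frequencies while staying invariant
    to the order the names are supplied in. Empty when no token qualifies.
    """
    names = list(names)
    if not names:
        raise ValueError("cluster has no member names")
    counts: Counter[str] = Counter()
    first_seen: dict[str, int] = {}
    for name in sorted(names):
        for tok in tokenize(name, excl):
            counts[tok] += 1
            first_seen.setdefault(tok, len(first_seen))
    qualifying = sorted(
        ((tok, cnt) for tok, cnt in counts.items() if cnt >= min_freq),
        key=lambda tc: (-tc[1], first_seen[tc[0]]),
    )
    title = " ".join(tok for tok, _ in qualifying[:top_k])
    return ClusterLabel(cluster_id, title, dict(counts))


def node_display_label(
    name: str,
    cluster_size: int,
    max_members_for_labels: int = 5,
) -> str | None:
    """Short display label for a node, or None in large clusters.

    Uses words 2..5 of the underscore-split name (the first word is
    typically the source library), removes literal ``_PATHWAY`` and
    ``_SIGNALING`` fragments, and renders remaining underscores as line
    breaks.
    """
    if cluster_size > max_members_for_labels:
        return None
    words = name.split("_")
    label = "_".join(words[1 : min(5, len(words))])
    label = label.replace("_PATHWAY", "").replace("_SIGNALING", "")
    return label.replace("_", "\n")


def format_title(title: str, max_len: int = 60) -> str:
    """Render a stored title for display: uppercase, truncated to
    ``max_len`` characters, with one optional line break inserted after a
    space between characters 10 and 30 when longer than 25 characters."""
    out = title.upper()[:max_len]
    if len(out) > 25:
        out = re.sub(r"^(.{10,30}) ", r"\1\n", out, count=1)
    return out
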