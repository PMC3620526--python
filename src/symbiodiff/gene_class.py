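"""Functional-ORF classification.

An annotated ORF counts as a functional gene when it conserves at least 80%
of the length of its closest ortholog, or when its essential functional
domains are intact (an externally supplied flag — domain scanning is an
upstream concern).  The two criteria are non-exclusionary (OR).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OrfEvidence", "classify_orf", "UnclassifiableError",
           "LENGTH_CONSERVATION_THRESHOLD"]

LENGTH_CONSERVATION_THRESHOLD = 0.80


class UnclassifiableError(ValueError):
    """Neither a usable ortholog length nor a domain flag is available."""


@dataclass
class OrfEvidence:
    orf_length: int
    ortholog_length: int | None = None     # nucleotide length of closest ortholog
    essential_domains_intact: bool | None = None

    def __post_init__(self) -> None:
        if self.orf_length <= 0:
            raise ValueError("orf_length must be positive")
        if self.ortholog_length is not None and self.ortholog_length <= 0:
            raise ValueError("ortholog_length must be positive")


def classify_orf(evidence: OrfEvidence) -> str:
    """Return 'functional' or 'pseudogene'.

    Functional iff length ratio >= 0.80 (boundary inclusive) OR the domain
    flag is true.  Raises UnclassifiableError when both pieces of evidence
    are missing.
    """
    has_ratio = evidence.ortholog_length is not None
    has_domains = evidence.essential_domains_intact is not None
    if not has_ratio and not has_domains:
        raise UnclassifiableError(
            "no ortholog length and no domain flag: ORF is unclassifiable")
    if has_ratio and \
            evidence.orf_length / evidence.ortholog_length >= LENGTH_CONSERVATION_THRESHOLD:
        return "functional"
    if has_domains and evidence.essential_domains_intact:
        return "functional"
    return "pseudogene"
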