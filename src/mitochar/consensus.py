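"""Cross-assembly correction of IUPAC-ambiguous sites.

A primary assembly (typically the only one that circularizes) may report a
handful of positions as degenerate IUPAC codes -- unresolved SNPs from the
read pool. Alternate assemblies of the same molecule, even fragmented ones,
usually show a definite base at those positions. This module resolves each
ambiguous site by *flank-anchored exact matching*: the unambiguous context of
``flank`` bases on either side of the site is located in every alternate
(both orientations, circularly where applicable), and each alternate votes
the base it shows between the matching flanks.

Voting policy (conservative): a unanimous vote wins; otherwise a strict
majority; a tie leaves the site unresolved. Votes incompatible with the
primary's IUPAC code are discarded and logged. An alternate whose flanks
match at more than one locus abstains, since placement ambiguity must not
create false votes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .genome import IUPAC_EXPANSION, SequenceRecord, reverse_complement

_UNAMBIGUOUS = frozenset("ACGT")


def locate_ambiguities(seq: str | SequenceRecord) -> list[tuple[int, str]]:
    """All (1-based position, code) pairs with non-ACGT codes, ascending."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    return [(i, ch) for i, ch in enumerate(residues, start=1) if ch not in _UNAMBIGUOUS]


@dataclass
class SiteResolution:
    """Outcome at one ambiguous position."""

    position: int
    primary_code: str
    votes: dict[str, str | None] = field(default_factory=dict)  # voter id -> base / None=abstain
    discarded: dict[str, str] = field(default_factory=dict)  # incompatible votes, logged
    resolution: str | None = None
    rule: str = "unresolved"  # unanimous | majority | single-source | unresolved
    note: str = ""


@dataclass
class ConsensusReport:
    sites: list[SiteResolution] = field(default_factory=list)

    @property
    def n_resolved(self) -> int:
        return sum(1 for s in self.sites if s.resolution is not None)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            rows.append(
                {
                    "position": s.position,
                    "primary_code": s.primary_code,
                    "votes": ";".join(
                        f"{k}={v if v is not None else '.'}" for k, v in sorted(s.votes.items())
                    ),
                    "resolution": s.resolution or "unresolved",
                    "rule": s.rule,
                    "note": s.note,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["position", "primary_code", "votes", "resolution", "rule", "note"],
        )


def _context(residues: str, pos: int, flank: int, circular: bool) -> tuple[str, str] | None:
    """Flank-length context on each side of 1-based ``pos``; None if truncated."""
    n = len(residues)
    if circular:
        doubled = residues + residues
        left = doubled[pos - 1 - flank + n : pos - 1 + n]
        right = doubled[pos : pos + flank]
    else:
        if pos - 1 < flank or n - pos < flank:
            return None
        left = residues[pos - 1 - flank : pos - 1]
        right = residues[pos : pos + flank]
    return left, right


def _find_votes(haystack: str, left: str, right: str) -> list[str]:
    """Bases appearing between exact flank matches in one linear string."""
    flank = len(left)
    votes = []
    start = 0
    while True:
        i = haystack.find(left, start)
        if i < 0:
            break
        j = i + flank + 1
        if haystack[j : j + flank] == right:
            votes.append(haystack[i + flank])
        start = i + 1
    return votes


def _alternate_vote(
    fragments: Sequence[SequenceRecord], left: str, right: str
) -> tuple[str | None, str]:
    """One assembly's vote: the base between flanks, or None with a reason."""
    hits: list[str] = []
    for frag in fragments:
        searchable = frag.residues + frag.residues[: 2 * len(left)] if frag.circular else frag.residues
        hits.extend(_find_votes(searchable, left, right))
        rc = reverse_complement(searchable)
        hits.extend(_find_votes(rc, left, right))
    if not hits:
        return None, "no flank match"
    if len(hits) > 1:
        # A circular self-overlap or repeat placed the context more than once.
        if len(set(hits)) == 1 and all(f.circular for f in fragments):
            return hits[0], ""
        return None, f"multiple flank matches ({len(hits)})"
    return hits[0], ""


def resolve_ambiguities(
    primary: SequenceRecord,
    alternates: Sequence[SequenceRecord | Sequence[SequenceRecord]],
    flank: int = 20,
) -> tuple[SequenceRecord, ConsensusReport]:
    """Resolve the primary assembly's ambiguous sites by alternate voting.

    Parameters
    ----------
    primary:
        The assembly to correct.
    alternates:
        One entry per alternate assembly. An entry may be a single
        :class:`SequenceRecord` or a sequence of records (a fragmented
        assembly); a fragmented assembly still casts a single vote per site.
    flank:
        Exact-match anchor length on each side of a site (>= 8).

    Returns
    -------
    (corrected record, report). Resolved positions are substituted; sites
    that stay unresolved keep their IUPAC code. Non-ambiguous positions are
    never altered.
    """
    if flank < 8:
        raise ValidationError(f"flank must be >= 8 (got {flank})")
    if not alternates:
        return replace(primary), ConsensusReport()
    voters: list[tuple[str, list[SequenceRecord]]] = []
    for k, alt in enumerate(alternates, start=1):
        frags = [alt] if isinstance(alt, SequenceRecord) else list(alt)
        label = frags[0].id if len(frags) == 1 else f"alt{k}({len(frags)} fragments)"
        voters.append((f"alt{k}:{label}", frags))

    report = ConsensusReport()
    residues = list(primary.residues)
    for pos, code in locate_ambiguities(primary):
        site = SiteResolution(position=pos, primary_code=code)
        ctx = _context(primary.residues, pos, flank, primary.circular)
        if ctx is None:
            site.note = "context truncated at sequence end"
            report.sites.append(site)
            continue
        left, right = ctx
        if not _UNAMBIGUOUS.issuperset(left + right):
            site.note = "flank context itself ambiguous"
            report.sites.append(site)
            continue
        expansion = set(IUPAC_EXPANSION[code])
        valid: list[str] = []
        for voter_id, frags in voters:
            base, reason = _alternate_vote(frags, left, right)
            if base is None:
                site.votes[voter_id] = None
                if reason:
                    site.note = (site.note + f"; {voter_id}: {reason}").lstrip("; ")
                continue
            if base not in expansion:
                site.discarded[voter_id] = base
                site.votes[voter_id] = None
                site.note = (
                    site.note + f"; {voter_id}: vote {base} incompatible with {code}, discarded"
                ).lstrip("; ")
                continue
            site.votes[voter_id] = base
            valid.append(base)

        if valid:
            counts = Counter(valid)
            top, top_n = counts.most_common(1)[0]
            if len(counts) == 1:
                site.resolution = top
                site.rule = "unanimous" if len(valid) > 1 else "single-source"
            elif top_n * 2 > len(valid):
                site.resolution = top
                site.rule = "majority"
            else:
                site.note = (site.note + "; tie among voters").lstrip("; ")
        report.sites.append(site)
        if site.resolution is not None:
            residues[pos - 1] = site.resolution

    corrected = replace(primary, residues="".join(residues))
    return corrected, report
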