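"""Proteomics bookkeeping: in-silico tryptic digestion, emPAI abundance,
replicate presence calls, nucleoporin census and Y-complex overlap.

Probabilistic search-engine validation is replaced by the deterministic
"at least two distinct peptides per replicate" rule; the observable-peptide
window is a length proxy (6-30 residues) rather than an m/z range.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .volume import ValidationError

__all__ = [
    "EmpaiRecord",
    "PresenceRecord",
    "tryptic_digest",
    "empai",
    "empai_table",
    "presence_table",
    "census",
    "y_complex_overlap",
    "load_ms_fixture",
    "load_y_complex_members",
    "load_nup_catalogue",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_LENGTH_RANGE = (6, 30)


@dataclass
class EmpaiRecord:
    protein_id: str
    n_observed: int
    n_observable: int
    empai: float


@dataclass
class PresenceRecord:
    protein_id: str
    detected_in: frozenset[int]
    n_replicates: int = 3

    @property
    def presence_string(self) -> str:
        return f"{len(self.detected_in)}/{self.n_replicates}"


def tryptic_digest(sequence: str, missed_cleavages: int = 0,
                   length_range: tuple[int, int] | None = DEFAULT_LENGTH_RANGE
                   ) -> set[str]:
    """Observable tryptic peptides: cleave after K or R unless followed by P.

    With ``length_range=None`` no length filter is applied; the unfiltered
    fragments concatenate back to the input sequence.
    """
    sequence = sequence.strip().upper()
    bad = set(sequence) - _VALID_AA
    if bad:
        raise ValidationError(
            f"illegal amino-acid characters {sorted(bad)} in sequence")
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    fragments = [m.group(0)
                 for m in re.finditer(r".*?[KR](?!P)|.+?$", sequence)] \
        if sequence else []
    peptides = set(fragments)
    for span in range(2, missed_cleavages + 2):
        for i in range(len(fragments) - span + 1):
            peptides.add("".join(fragments[i:i + span]))
    if length_range is not None:
        lo, hi = length_range
        peptides = {p for p in peptides if lo <= len(p) <= hi}
        if not peptides and sequence:
            import warnings
            warnings.warn("length filter excluded every peptide", stacklevel=2)
    return peptides


def empai(n_observed: int, n_observable: int) -> float:
    """Exponentially modified protein abundance index:
    ``10^(n_observed / n_observable) - 1``."""
    if n_observable < 1:
        raise ValidationError("n_observable must be >= 1")
    if not 0 <= n_observed <= n_observable:
        raise ValidationError(
            f"need 0 <= n_observed <= n_observable, got "
            f"({n_observed}, {n_observable})")
    return 10.0 ** (n_observed / n_observable) - 1.0


def empai_table(peptides: pd.DataFrame, catalogue: dict[str, str],
                length_range=DEFAULT_LENGTH_RANGE) -> list[EmpaiRecord]:
    """Per-protein emPAI from a peptide detection table (all replicates
    pooled) and a sequence catalogue defining the observable peptides."""
    records = []
    observed = peptides.groupby("protein_id")["peptide"].nunique()
    for pid in sorted(catalogue):
        observable = len(tryptic_digest(catalogue[pid],
                                        length_range=length_range))
        if observable == 0:
            continue
        n_obs = int(observed.get(pid, 0))
        n_obs = min(n_obs, observable)
        records.append(EmpaiRecord(pid, n_obs, observable,
                                   empai(n_obs, observable)))
    return records


def presence_table(peptides: pd.DataFrame, min_peptides: int = 2,
                   n_replicates: int = 3) -> list[PresenceRecord]:
    """A protein is detected in a replicate iff at least ``min_peptides``
    distinct peptides were observed there."""
    if min_peptides < 1:
        raise ValidationError("min_peptides must be >= 1")
    counts = (peptides.groupby(["protein_id", "replicate"])["peptide"]
              .nunique())
    detected: dict[str, set[int]] = {}
    for (pid, rep), n in counts.items():
        if n >= min_peptides:
            detected.setdefault(pid, set()).add(int(rep))
    return [PresenceRecord(pid, frozenset(reps), n_replicates)
            for pid, reps in sorted(detected.items())]


def census(presence, nup_catalogue) -> dict:
    """Count catalogue proteins detected in at least one replicate, plus a
    per-presence histogram (e.g. {"3/3": 25, ...})."""
    catalogue = set(nup_catalogue)
    histogram: dict[str, int] = {}
    detected = []
    for rec in presence:
        if rec.protein_id not in catalogue or not rec.detected_in:
            continue
        detected.append(rec.protein_id)
        key = rec.presence_string
        histogram[key] = histogram.get(key, 0) + 1
    return {"n_detected": len(detected),
            "detected": sorted(detected),
            "histogram": dict(sorted(histogram.items()))}


def y_complex_overlap(set_a, set_b, homologue_map=None):
    """Shared members of two Y-complex lists after homologue renaming.

    Returns ``(shared, count, only_a, only_b)`` with names in B's namespace
    where the map applies.
    """
    if not set_a or not set_b:
        raise ValidationError("both member sets must be non-empty")
    mapping = dict(homologue_map or {})
    mapped_a = {mapping.get(name, name) for name in set_a}
    b = set(set_b)
    shared = sorted(mapped_a & b)
    return shared, len(shared), sorted(mapped_a - b), sorted(b - mapped_a)


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

def load_ms_fixture() -> pd.DataFrame:
    """The packaged replicate detection table (read-only in-paper data)."""
    with resources.files("npckit.data").joinpath(
            "ms_detections.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def _load_members() -> dict:
    text = resources.files("npckit.data").joinpath(
        "y_complex_members.json").read_text()
    return json.loads(text)


def load_y_complex_members() -> tuple[list[str], list[str], dict[str, str]]:
    data = _load_members()
    return data["arabidopsis"], data["human"], data["homologue_map"]


def load_nup_catalogue() -> list[str]:
    return _load_members()["nup_catalogue"]


def presence_from_fixture(fixture: pd.DataFrame) -> list[PresenceRecord]:
    """Presence records from the fixture's per-replicate emPAI values
    (a protein is present in a replicate iff its emPAI there is > 0)."""
    records = []
    for row in fixture.itertuples(index=False):
        reps = {i for i in (1, 2, 3)
                if getattr(row, f"empai_{i}") > 0}
        rec = PresenceRecord(row.protein, frozenset(reps))
        if rec.presence_string != row.presence:
            raise ValidationError(
                f"{row.protein}: fixture presence column {row.presence!r} "
                f"inconsistent with emPAI values ({rec.presence_string})")
        records.append(rec)
    return records
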