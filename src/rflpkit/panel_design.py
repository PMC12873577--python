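"""Minimal marker-panel selection and cut-pattern authentication.

Each candidate marker is one bit of information per strain: its restriction
site is either cut or not cut.  A panel of *k* markers can therefore encode
at most 2^k strains, and a set of *n* strains needs at least ceil(log2 n)
markers — the dichotomous-key, power-of-two bound.  Selection is a greedy
loop that at each step picks the marker splitting the worst remaining
ambiguity class, with an exhaustive search available as an oracle on small
candidate sets.  Authentication maps an observed (possibly partial)
cut/no-cut pattern back to the consistent strain(s).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .restriction import AlleleSiteStatus
from .variant_store import Call, GenotypeMatrix, Variant


def required_marker_count(n_strains: int) -> int:
    """Smallest k with 2**k >= n_strains, i.e. ceil(log2 n_strains).

    One strain needs no markers; 10 strains need 4 (2^4 = 16 >= 10).
    """
    if n_strains < 1:
        raise ValueError(f"n_strains must be >= 1, got {n_strains}")
    return (n_strains - 1).bit_length()


def panel_capacity(k_markers: int) -> int:
    """Number of distinct cut patterns k binary markers can produce: 2**k."""
    if k_markers < 0:
        raise ValueError(f"k_markers must be >= 0, got {k_markers}")
    return 2 ** k_markers


@dataclass
class CutPatternMatrix:
    """Strains x candidate markers cut/no-cut table.

    ``cut[i, j]`` is True iff strain ``strains[j]`` carries the cut allele of
    marker ``markers[i]``.  ``variants`` optionally carries the underlying
    VCF site per marker for export.
    """

    strains: list[str]
    markers: list[str]
    cut: np.ndarray  # (n_markers, n_strains) bool
    variants: Optional[list[Variant]] = None

    def __post_init__(self) -> None:
        self.cut = np.asarray(self.cut, dtype=bool)
        if self.cut.shape != (len(self.markers), len(self.strains)):
            raise ValueError(
                f"cut shape {self.cut.shape} != "
                f"({len(self.markers)}, {len(self.strains)})"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker identifiers")

    @property
    def informative(self) -> np.ndarray:
        """Per-marker mask: at least one strain cut and one uncut."""
        return self.cut.any(axis=1) & (~self.cut).any(axis=1)

    def cut_strains(self, marker: str) -> list[str]:
        row = self.cut[self.markers.index(marker)]
        return [s for s, c in zip(self.strains, row) if c]

    @classmethod
    def from_cut_sets(cls, strains: Sequence[str],
                      cut_sets: Mapping[str, Iterable[str]]
                      ) -> "CutPatternMatrix":
        """Build from a {marker: strains-that-cut} mapping (the shape of a
        published "Which strains are cut?" table column)."""
        strains = list(strains)
        markers = list(cut_sets)
        cut = np.zeros((len(markers), len(strains)), dtype=bool)
        for i, mk in enumerate(markers):
            for s in cut_sets[mk]:
                cut[i, strains.index(s)] = True
        return cls(strains=strains, markers=markers, cut=cut)

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix,
                       statuses: Sequence[AlleleSiteStatus]
                       ) -> "CutPatternMatrix":
        """Combine homozygous genotypes with per-allele site status.

        Keeps only discriminating variants (exactly one allele cut).  A
        strain is "cut" at a marker iff its homozygous allele is the cut
        allele.  ``gm`` must already be filtered to clean biallelic SNPs.
        """
        if len(statuses) != gm.n_variants:
            raise ValueError("one AlleleSiteStatus per variant required")
        markers, rows, variants = [], [], []
        for i, (v, st) in enumerate(zip(gm.variants, statuses)):
            if not st.discriminating:
                continue
            is_alt = gm.calls[i] == Call.ALT_HOM
            rows.append(is_alt if st.alt_cut else ~is_alt)
            markers.append(v.key)
            variants.append(v)
        cut = (np.array(rows, dtype=bool) if rows
               else np.empty((0, gm.n_strains), dtype=bool))
        return cls(strains=list(gm.strains), markers=markers, cut=cut,
                   variants=variants)


def _codes(m: CutPatternMatrix, marker_ids: Sequence[str]) -> dict[str, tuple]:
    idx = []
    for mk in marker_ids:
        try:
            idx.append(m.markers.index(mk))
        except ValueError:
            raise KeyError(f"unknown marker ID {mk!r}") from None
    return {s: tuple(m.cut[i, j] for i in idx)
            for j, s in enumerate(m.strains)}


def ambiguity_groups(m: CutPatternMatrix,
                     marker_subset: Sequence[str]) -> list[list[str]]:
    """Strain groups sharing identical codes over ``marker_subset``.

    Only non-singleton classes are returned, each sorted, the list ordered
    by each group's smallest member.  An empty subset puts every strain in
    one group (no information yet).
    """
    by_code: dict[tuple, list[str]] = {}
    for s, code in _codes(m, marker_subset).items():
        by_code.setdefault(code, []).append(s)
    groups = [sorted(g) for g in by_code.values() if len(g) >= 2]
    return sorted(groups, key=lambda g: g[0])


def _pair_count(groups: list[list[str]]) -> int:
    return sum(len(g) * (len(g) - 1) // 2 for g in groups)


@dataclass
class MarkerPanel:
    """An ordered marker selection with per-strain binary codes.

    ``codes`` maps each strain to its bit string in panel order ('1' = cut).
    ``tiers`` maps each panel marker to the strain groups it is required to
    separate: the groups that would share a code if that marker were removed
    from the panel.  ``optional_for`` lists, per marker, the strains whose
    code stays unique without it (the dichotomous-key "this marker can be
    skipped for those strains" annotation).  ``residual`` holds any strain
    groups the panel could not separate.
    """

    markers: list[str]
    codes: dict[str, str]
    tiers: dict[str, list[list[str]]] = field(default_factory=dict)
    optional_for: dict[str, list[str]] = field(default_factory=dict)
    residual: list[list[str]] = field(default_factory=list)
    variants: Optional[list[Variant]] = None

    def __post_init__(self) -> None:
        if self.resolved:
            vals = list(self.codes.values())
            if len(set(vals)) != len(vals):
                raise ValueError("panel marked resolved but codes collide")

    @property
    def resolved(self) -> bool:
        return not self.residual

    @property
    def strains(self) -> list[str]:
        return list(self.codes)

    def to_dict(self) -> dict:
        d = {"markers": self.markers, "codes": self.codes,
             "tiers": self.tiers, "optional_for": self.optional_for,
             "residual": self.residual}
        if self.variants is not None:
            d["variants"] = [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref_allele,
                 "alt": v.alt_allele, "id": v.vid}
                for v in self.variants
            ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "MarkerPanel":
        variants = None
        if "variants" in d:
            variants = [Variant(x["chrom"], x["pos"], x["ref"], x["alt"],
                                vid=x.get("id")) for x in d["variants"]]
        return cls(markers=list(d["markers"]), codes=dict(d["codes"]),
                   tiers={k: [list(g) for g in v]
                          for k, v in d.get("tiers", {}).items()},
                   optional_for={k: list(v)
                                 for k, v in d.get("optional_for", {}).items()},
                   residual=[list(g) for g in d.get("residual", [])],
                   variants=variants)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "MarkerPanel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def select_panel(m: CutPatternMatrix,
                 ranking: Optional[Union[Sequence[str], Mapping[str, float]]]
                 = None) -> MarkerPanel:
    """Greedily select markers until every strain's code is unique.

    At each step the candidate minimizing the size of the largest remaining
    ambiguity group is added; ties are broken by fewest unresolved strain
    pairs, then by higher caller-supplied ``ranking`` (a priority-ordered
    marker list or a marker->score mapping), then by lexicographic marker
    ID.  The loop stops when no ambiguity remains or no candidate improves;
    leftover groups are reported as ``residual`` rather than raising.
    """
    if len(m.strains) == 0:
        raise ValueError("empty strain set")
    if ranking is None:
        prio = {}
    elif isinstance(ranking, Mapping):
        prio = dict(ranking)
    else:
        prio = {mk: -i for i, mk in enumerate(ranking)}

    usable = [mk for mk, ok in zip(m.markers, m.informative) if ok]
    chosen: list[str] = []
    groups = ambiguity_groups(m, chosen)
    while groups:
        cur_key = (max(len(g) for g in groups), _pair_count(groups))
        best = None
        for mk in usable:
            if mk in chosen:
                continue
            g2 = ambiguity_groups(m, chosen + [mk])
            key = (max((len(g) for g in g2), default=1), _pair_count(g2),
                   -prio.get(mk, 0.0), mk)
            if best is None or key < best[0]:
                best = (key, mk, g2)
        if best is None or best[0][:2] >= cur_key:
            break  # no marker improves
        chosen.append(best[1])
        groups = best[2]

    codes = {s: "".join("1" if b else "0" for b in code)
             for s, code in _codes(m, chosen).items()}
    tiers, optional = {}, {}
    for mk in chosen:
        without = [c for c in chosen if c != mk]
        g_without = ambiguity_groups(m, without)
        g_full = {tuple(g) for g in groups}
        # groups this marker is required to separate = ambiguous without it
        # but not ambiguous with the full panel
        tiers[mk] = [g for g in g_without if tuple(g) not in g_full]
        tied = {s for g in g_without for s in g}
        optional[mk] = sorted(s for s in m.strains if s not in tied)
    panel = MarkerPanel(markers=chosen, codes=codes, tiers=tiers,
                        optional_for=optional, residual=groups)
    if m.variants is not None:
        vmap = dict(zip(m.markers, m.variants))
        panel.variants = [vmap[mk] for mk in chosen]
    return panel


def exhaustive_min_panel(m: CutPatternMatrix,
                         max_candidates: int = 20) -> Optional[list[str]]:
    """Smallest marker subset giving pairwise-distinct codes, by brute force.

    Intended as an optimality oracle on small candidate sets; returns None
    if no subset (including the full set) resolves all strains.
    """
    usable = [mk for mk, ok in zip(m.markers, m.informative) if ok]
    if len(usable) > max_candidates:
        raise ValueError(
            f"{len(usable)} candidates exceed exhaustive-search cap "
            f"{max_candidates}"
        )
    lo = required_marker_count(len(m.strains))
    for k in range(lo, len(usable) + 1):
        for combo in itertools.combinations(usable, k):
            if not ambiguity_groups(m, list(combo)):
                return list(combo)
    return None


# ---------------------------------------------------------------------------
# Authentication
# ---------------------------------------------------------------------------

CUT, UNCUT, UNTESTED = True, False, None

_STATE_ALIASES = {
    "cut": True, "c": True, "1": True, "yes": True, "true": True,
    "not": False, "uncut": False, "no-cut": False, "nocut": False,
    "n": False, "0": False, "no": False, "false": False,
    "untested": None, "?": None, "-": None, "na": None, "": None,
}


def parse_pattern(pattern: Union[str, Sequence]) -> list[Optional[bool]]:
    """Normalize an observed pattern to a list of True/False/None.

    Accepts a comma-separated string (``"cut,not,cut,untested"``), a bare
    bit string (``"1010"``, '?' = untested), or any sequence of
    bools/Nones/state words.
    """
    if isinstance(pattern, str):
        if "," not in pattern and set(pattern) <= {"0", "1", "?"}:
            pattern = list(pattern)
        else:
            pattern = [p.strip() for p in pattern.split(",")]
    out: list[Optional[bool]] = []
    for p in pattern:
        if p is None or isinstance(p, bool):
            out.append(p)
        elif isinstance(p, (int, np.integer)):
            out.append(bool(p))
        else:
            key = str(p).strip().lower()
            if key not in _STATE_ALIASES:
                raise ValueError(f"unrecognized cut state {p!r}")
            out.append(_STATE_ALIASES[key])
    return out


@dataclass(frozen=True)
class AuthenticationResult:
    """Outcome of decoding an observed cut pattern against a panel.

    MATCH: exactly one strain consistent; AMBIGUOUS: several (``candidates``
    lists them); NO_MATCH: none — the sample matches no panel strain,
    signalling mislabeling or contamination.
    """

    status: str  # MATCH | AMBIGUOUS | NO_MATCH
    matched_strain: Optional[str]
    candidates: list[str]
    markers_consulted: list[str]

    def to_dict(self) -> dict:
        return {"status": self.status, "matched_strain": self.matched_strain,
                "candidates": self.candidates,
                "markers_consulted": self.markers_consulted}


def authenticate(panel: MarkerPanel,
                 observed: Union[str, Sequence]) -> AuthenticationResult:
    """Decode an observed (possibly partial) cut pattern to strain identity.

    ``observed`` may be shorter than the panel (the remaining markers are
    untested — dichotomous-key usage) and may contain explicit ``untested``
    positions.  A strain is consistent iff its code agrees at every tested
    position.
    """
    states = parse_pattern(observed)
    if len(states) > len(panel.markers):
        raise ValueError(
            f"observed pattern has {len(states)} states but panel has "
            f"{len(panel.markers)} markers"
        )
    states = states + [None] * (len(panel.markers) - len(states))
    tested = [i for i, st in enumerate(states) if st is not None]
    consistent = sorted(
        s for s, code in panel.codes.items()
        if all((code[i] == "1") == states[i] for i in tested)
    )
    if len(consistent) == 1:
        status, match = "MATCH", consistent[0]
    elif consistent:
        status, match = "AMBIGUOUS", None
    else:
        status, match = "NO_MATCH", None
    return AuthenticationResult(
        status=status, matched_strain=match, candidates=consistent,
        markers_consulted=[panel.markers[i] for i in tested],
    )


def panel_tsv(panel: MarkerPanel, m: Optional[CutPatternMatrix] = None) -> str:
    """Serialize a panel as TSV (marker, chrom, pos, alleles, cut strains).

    Mirrors the layout of a published primer table's site columns; primer
    columns are added by the assay sheet in :mod:`rflpkit.assay_design`.
    """
    lines = ["marker\tchrom\tpos\tref\talt\tcut_strains"]
    for i, mk in enumerate(panel.markers):
        v = panel.variants[i] if panel.variants else None
        cut = (m.cut_strains(mk) if m is not None
               else [s for s in panel.codes if panel.codes[s][i] == "1"])
        lines.append("\t".join([
            mk,
            v.chrom if v else ".", str(v.pos) if v else ".",
            v.ref_allele if v else ".", v.alt_allele if v else ".",
            ",".join(cut),
        ]))
    return "\n".join(lines) + "\n"
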