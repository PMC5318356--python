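"""Domain types and I/O for arm-level migraine-prophylaxis trial data.

The evidence base is a network of randomized trials over seven
interventions (placebo plus six prophylactic drugs) evaluated on nine
endpoints: two continuous outcomes analysed as raw mean differences
(monthly migraine headache days, headache frequency) and seven binary
outcomes analysed as odds ratios (treatment response, adverse events,
withdrawals).  One CSV row encodes one treatment arm of one study for one
endpoint (long format), because individual trials report only a subset of
the endpoints.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Treatment",
    "Endpoint",
    "ArmRecord",
    "EvidenceNetwork",
    "StudyMeta",
    "SchemaError",
    "ValidationError",
    "DisconnectedNetworkError",
    "TREATMENTS",
    "ENDPOINTS",
    "REFERENCE",
    "treatment",
    "endpoint",
    "read_arm_table",
    "write_arm_table",
    "build_network",
    "direct_comparisons",
    "load_fixture",
    "fixture_summary",
    "ARM_CSV_COLUMNS",
]


class SchemaError(ValueError):
    """The input table does not match the expected column contract."""


class ValidationError(ValueError):
    """A row violates an arm-record invariant."""


class DisconnectedNetworkError(ValueError):
    """The evidence network does not form a single connected component."""

    def __init__(self, components):
        self.components = [frozenset(c) for c in components]
        pretty = "; ".join(
            "{" + ",".join(sorted(t.code for t in c)) + "}" for c in self.components
        )
        super().__init__(
            f"evidence network is disconnected (cannot form a closed network): "
            f"components {pretty}"
        )


@dataclass(frozen=True, order=True)
class Treatment:
    """An intervention node, labelled A-G as in the network plots."""

    code: str
    name: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


#: The seven-intervention universe; A is the reference (placebo).
TREATMENTS: dict[str, Treatment] = {
    code: Treatment(code, name)
    for code, name in [
        ("A", "placebo"),
        ("B", "topiramate"),
        ("C", "propranolol"),
        ("D", "gabapentin"),
        ("E", "amitriptyline"),
        ("F", "divalproex"),
        ("G", "valproate"),
    ]
}
_TREATMENT_BY_NAME = {t.name: t for t in TREATMENTS.values()}
REFERENCE: Treatment = TREATMENTS["A"]


def treatment(key: str, allow_new: bool = False) -> Treatment:
    """Resolve a treatment by letter code or (case-folded) name.

    Unknown names are rejected so the seven-node universe stays fixed,
    unless ``allow_new`` is set, in which case a new node with a
    synthesised code is returned.
    """
    k = key.strip()
    if k.upper() in TREATMENTS and len(k) == 1:
        return TREATMENTS[k.upper()]
    name = k.casefold()
    if name in _TREATMENT_BY_NAME:
        return _TREATMENT_BY_NAME[name]
    if allow_new:
        return Treatment(code=name[:1].upper() + "*", name=name)
    raise ValidationError(
        f"unknown treatment {key!r}; pass allow_new=True to extend the network"
    )


@dataclass(frozen=True)
class Endpoint:
    """A clinical outcome with its analysis scale and benefit direction."""

    code: int
    name: str
    scale: str  # "continuous_MD" | "binary_OR"
    direction: str  # "higher_is_better" | "lower_is_better"

    @property
    def is_binary(self) -> bool:
        return self.scale == "binary_OR"


#: The nine endpoints: 1-2 continuous mean differences, 3-9 binary odds
#: ratios; only the 50%-responder endpoint counts a larger effect as better.
ENDPOINTS: dict[int, Endpoint] = {
    e.code: e
    for e in [
        Endpoint(1, "migraine_headache_days", "continuous_MD", "lower_is_better"),
        Endpoint(2, "headache_frequency", "continuous_MD", "lower_is_better"),
        Endpoint(3, "responder_50pct", "binary_OR", "higher_is_better"),
        Endpoint(4, "all_adverse_events", "binary_OR", "lower_is_better"),
        Endpoint(5, "nausea", "binary_OR", "lower_is_better"),
        Endpoint(6, "somnolence", "binary_OR", "lower_is_better"),
        Endpoint(7, "dizziness", "binary_OR", "lower_is_better"),
        Endpoint(8, "withdrawal", "binary_OR", "lower_is_better"),
        Endpoint(9, "withdrawal_due_to_aes", "binary_OR", "lower_is_better"),
    ]
}
_ENDPOINT_BY_NAME = {e.name: e for e in ENDPOINTS.values()}


def endpoint(key) -> Endpoint:
    """Resolve an endpoint by integer code (1-9) or canonical name."""
    if isinstance(key, Endpoint):
        return key
    try:
        return ENDPOINTS[int(key)]
    except (ValueError, TypeError, KeyError):
        pass
    name = str(key).strip().casefold()
    if name in _ENDPOINT_BY_NAME:
        return _ENDPOINT_BY_NAME[name]
    raise ValidationError(f"unknown endpoint {key!r}")


@dataclass(frozen=True)
class ArmRecord:
    """One treatment arm of one study for one endpoint.

    Binary endpoints carry ``events`` out of ``n`` randomized; continuous
    endpoints carry ``mean``/``sd`` of the arm outcome.  Exactly one of the
    two groups is populated, matching the endpoint scale.
    """

    study_id: str
    year: int
    design: str  # "parallel" | "crossover"
    blinding: str  # "single" | "double"
    endpoint: Endpoint
    treatment: Treatment
    n: int
    events: Optional[int] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    follow_up_weeks: Optional[float] = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"{self.study_id}: n must be >= 1, got {self.n}")
        if self.design not in ("parallel", "crossover"):
            raise ValidationError(f"{self.study_id}: bad design {self.design!r}")
        if self.blinding not in ("single", "double"):
            raise ValidationError(f"{self.study_id}: bad blinding {self.blinding!r}")
        if self.endpoint.is_binary:
            if self.events is None or self.mean is not None or self.sd is not None:
                raise ValidationError(
                    f"{self.study_id}: binary endpoint {self.endpoint.name} "
                    f"requires events only"
                )
            if not 0 <= self.events <= self.n:
                raise ValidationError(
                    f"{self.study_id}: events={self.events} outside [0, n={self.n}]"
                )
        else:
            if self.mean is None or self.sd is None or self.events is not None:
                raise ValidationError(
                    f"{self.study_id}: continuous endpoint {self.endpoint.name} "
                    f"requires mean and sd only"
                )
            if not self.sd > 0:
                raise ValidationError(f"{self.study_id}: sd must be > 0, got {self.sd}")


@dataclass
class EvidenceNetwork:
    """Treatments as nodes, studies as edges, for one endpoint."""

    endpoint: Endpoint
    treatments: set[Treatment]
    studies: dict[str, list[ArmRecord]]
    edges: dict[frozenset, list[str]] = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for pair, sids in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, studies=list(sids))
        return g

    @property
    def n_studies(self) -> int:
        return len(self.studies)


@dataclass(frozen=True)
class StudyMeta:
    """One row of the packaged 32-study evidence table."""

    study_id: str
    year: int
    design: str
    blinding: str
    interventions: tuple[Treatment, Treatment]
    size: int
    male_pct: float
    follow_up: str  # as printed in the source table; units are inconsistent
    endpoints_measured: frozenset[int]

    def __post_init__(self):
        if self.size <= 0:
            raise ValidationError(f"{self.study_id}: non-positive size")


ARM_CSV_COLUMNS = [
    "study_id",
    "year",
    "design",
    "blinding",
    "endpoint",
    "treatment",
    "n",
    "events",
    "mean",
    "sd",
    "follow_up_weeks",
]


def read_arm_table(path, allow_new_treatments: bool = False) -> list[ArmRecord]:
    """Read a long-format arm-level CSV, validating every row.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` (naming the study) for invariant violations
    such as events > n or sd <= 0.  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ARM_CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        records = []
        for row in reader:
            ep = endpoint(row["endpoint"])

            def opt(key, cast):
                val = row.get(key, "")
                return cast(val) if val not in ("", None) else None

            records.append(
                ArmRecord(
                    study_id=row["study_id"],
                    year=int(row["year"]),
                    design=row["design"].strip().casefold(),
                    blinding=row["blinding"].strip().casefold(),
                    endpoint=ep,
                    treatment=treatment(row["treatment"], allow_new=allow_new_treatments),
                    n=int(row["n"]),
                    events=opt("events", lambda v: int(float(v))),
                    mean=opt("mean", float),
                    sd=opt("sd", float),
                    follow_up_weeks=opt("follow_up_weeks", float),
                )
            )
    return records


def write_arm_table(records: Iterable[ArmRecord], path) -> None:
    """Write arm records to CSV under the same contract ``read_arm_table`` reads."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ARM_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.study_id,
                    r.year,
                    r.design,
                    r.blinding,
                    r.endpoint.code,
                    r.treatment.name,
                    r.n,
                    "" if r.events is None else r.events,
                    "" if r.mean is None else repr(float(r.mean)),
                    "" if r.sd is None else repr(float(r.sd)),
                    "" if r.follow_up_weeks is None else repr(float(r.follow_up_weeks)),
                ]
            )


def build_network(arms: Iterable[ArmRecord], ep) -> EvidenceNetwork:
    """Assemble the evidence network for one endpoint.

    Studies contributing arms for only one treatment on this endpoint are
    dropped (with a logged warning).  A disconnected result raises
    :class:`DisconnectedNetworkError` listing the components, mirroring the
    closed-network eligibility requirement.
    """
    ep = endpoint(ep)
    by_study: dict[str, list[ArmRecord]] = defaultdict(list)
    for rec in arms:
        if rec.endpoint == ep:
            by_study[rec.study_id].append(rec)
    if not by_study:
        raise ValidationError(f"no study measures endpoint {ep.name}")

    studies: dict[str, list[ArmRecord]] = {}
    for sid, recs in by_study.items():
        treats = {r.treatment for r in recs}
        if len(treats) < 2:
            logger.warning(
                "dropping study %s for endpoint %s: only one treatment arm", sid, ep.name
            )
            continue
        if len(treats) != len(recs):
            raise ValidationError(f"{sid}: duplicate treatment arms for {ep.name}")
        studies[sid] = sorted(recs, key=lambda r: r.treatment.code)
    if not studies:
        raise ValidationError(f"no multi-arm study measures endpoint {ep.name}")

    edges: dict[frozenset, list[str]] = defaultdict(list)
    nodes: set[Treatment] = set()
    for sid, recs in sorted(studies.items()):
        treats = [r.treatment for r in recs]
        nodes.update(treats)
        for a, b in combinations(treats, 2):
            edges[frozenset((a, b))].append(sid)

    net = EvidenceNetwork(endpoint=ep, treatments=nodes, studies=studies, edges=dict(edges))
    g = net.graph()
    if not nx.is_connected(g):
        raise DisconnectedNetworkError(nx.connected_components(g))
    return net


def direct_comparisons(network: EvidenceNetwork) -> set[frozenset]:
    """The set of unordered treatment pairs with head-to-head evidence."""
    return set(network.edges)


# ---------------------------------------------------------------------------
# Packaged 32-study evidence table


def load_fixture() -> list[StudyMeta]:
    """Load the packaged transcription of the 32-study evidence base."""
    with resources.files("migranet.data").joinpath("table1_fixture.csv").open(
        newline=""
    ) as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        out.append(
            StudyMeta(
                study_id=row["study_id"],
                year=int(row["year"]),
                design=row["design"],
                blinding=row["blinding"],
                interventions=(
                    treatment(row["treatment_1"]),
                    treatment(row["treatment_2"]),
                ),
                size=int(row["size"]),
                male_pct=float(row["male_pct"]),
                follow_up=row["follow_up"],
                endpoints_measured=frozenset(
                    int(c) for c in row["endpoints"].split(";")
                ),
            )
        )
    return out


def fixture_summary(fixture: Optional[list[StudyMeta]] = None) -> dict:
    """Exact integer summary of the evidence base: counts, size, comparisons."""
    if fixture is None:
        fixture = load_fixture()
    pairs = {frozenset(m.interventions) for m in fixture}
    return {
        "n_studies": len(fixture),
        "total_size": sum(m.size for m in fixture),
        "n_crossover": sum(1 for m in fixture if m.design == "crossover"),
        "pairs": pairs,
        "n_comparisons": len(pairs),
    }
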