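"""Message pool for a tailored SMS brief-message intervention.

The intervention draws from three kinds of content:

* **BCT messages** — short texts each operationalising a behaviour change
  technique (BCT); interchangeable texts are grouped by technique
  (e.g. ``1.4 Action Planning``).  Group ``i`` holds ``n_i`` texts; the
  pool holds ``t`` groups and ``n = sum(n_i)`` BCT texts in total.
* **Lifestyle messages** — general healthy-living advice, interleaved with
  the BCT stream at a ratio of one lifestyle text per ``q`` consecutive
  BCT texts.
* **Control messages** — condition-irrelevant content sent roughly monthly
  to a control arm (two-arm feasibility design only).

Two study variants are modelled: a single-arm *pilot* (157 BCT messages in
30 groups, 35 lifestyle, ``q = 5``) and a two-arm randomised *feasibility*
study (170 BCT messages in 30 groups, 35 lifestyle, 6 control, ``q = 2``).
The fixture generator reproduces those compositions with synthetic
placeholder bodies, so the whole pipeline can run without the studies'
copyrighted message texts.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

KINDS = ("bct", "lifestyle", "control")
STUDIES = ("pilot", "feasibility")

#: Pool composition per study variant:
#: (bct messages, bct groups, lifestyle, control, interleave q)
STUDY_COMPOSITION = {
    "pilot": (157, 30, 35, 0, 5),
    "feasibility": (170, 30, 35, 6, 2),
}

# BCT taxonomy-style group labels.  The first four are technique names that
# appear in published message examples; the rest are standard taxonomy
# categories used to fill out the 30 groups.
BCT_GROUP_LABELS = [
    "1.4 Action Planning",
    "2.3 Selfmonitoring",
    "7.1 Prompts or cues",
    "G Health care system related concerns",
    "1.1 Goal setting (behavior)",
    "1.2 Problem solving",
    "1.3 Goal setting (outcome)",
    "1.5 Review behavior goals",
    "1.6 Discrepancy between behavior and goal",
    "2.2 Feedback on behavior",
    "2.4 Self-monitoring of outcomes",
    "3.1 Social support (unspecified)",
    "3.2 Social support (practical)",
    "4.1 Instruction on how to perform the behavior",
    "4.2 Information about antecedents",
    "5.1 Information about health consequences",
    "5.3 Information about social consequences",
    "5.6 Information about emotional consequences",
    "6.1 Demonstration of the behavior",
    "8.1 Behavioral practice",
    "8.2 Behavior substitution",
    "8.3 Habit formation",
    "9.1 Credible source",
    "9.2 Pros and cons",
    "10.4 Social reward",
    "11.2 Reduce negative emotions",
    "12.1 Restructuring the physical environment",
    "12.5 Adding objects to the environment",
    "13.2 Framing and reframing",
    "15.1 Verbal persuasion about capability",
]

MAX_BODY_CHARS = 320  # two concatenated 160-char SMS parts


@dataclass(frozen=True)
class Message:
    """One SMS text in the pool."""

    message_id: str
    body: str
    kind: str  # bct | lifestyle | control
    group_id: str | None = None  # required iff kind == "bct"
    study: str = "both"  # pilot | feasibility | both


@dataclass
class BCTGroup:
    """A behaviour change technique group: interchangeable texts for one BCT."""

    group_id: str
    label: str
    members: list[Message] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.message_id for m in self.members]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MessageLibrary:
    """The full message pool {B_1..B_t, lifestyle, control} for one study."""

    study: str
    groups: list[BCTGroup]
    lifestyle: list[Message]
    control: list[Message] = field(default_factory=list)
    interleave_q: int = 5

    @property
    def t(self) -> int:
        """Number of BCT groups."""
        return len(self.groups)

    @property
    def n(self) -> int:
        """Total number of BCT messages (sum of group sizes)."""
        return sum(g.size for g in self.groups)

    @property
    def m(self) -> int:
        """Number of lifestyle messages."""
        return len(self.lifestyle)

    def group(self, group_id: str) -> BCTGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"unknown BCT group {group_id!r}")

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def all_messages(self) -> list[Message]:
        out: list[Message] = []
        for g in self.groups:
            out.extend(g.members)
        out.extend(self.lifestyle)
        out.extend(self.control)
        return out

    def message(self, message_id: str) -> Message:
        for m in self.all_messages():
            if m.message_id == message_id:
                return m
        raise KeyError(f"unknown message {message_id!r}")


class LibraryError(ValueError):
    """Raised when a library file cannot be parsed or fails validation."""


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_library(lib: MessageLibrary) -> list[str]:
    """Check every library invariant; return a list of violation descriptions.

    An empty list means the library is valid.  Violations are returned as
    data rather than raised, so callers can report all of them at once.
    """
    violations: list[str] = []
    if lib.study not in STUDIES:
        violations.append(f"unknown study {lib.study!r}")
    if lib.interleave_q < 1:
        violations.append(f"interleave_q must be >= 1, got {lib.interleave_q}")
    if lib.study == "pilot" and lib.control:
        violations.append(
            f"pilot library must have no control messages, found {len(lib.control)}"
        )

    seen: set[str] = set()
    for msg in lib.all_messages():
        if msg.message_id in seen:
            violations.append(f"duplicate message_id {msg.message_id!r}")
        seen.add(msg.message_id)
        if not msg.body:
            violations.append(f"message {msg.message_id!r} has an empty body")
        elif len(msg.body) > MAX_BODY_CHARS:
            violations.append(
                f"message {msg.message_id!r} body exceeds {MAX_BODY_CHARS} characters"
            )
        if msg.kind not in KINDS:
            violations.append(f"message {msg.message_id!r} has unknown kind {msg.kind!r}")
        if (msg.kind == "bct") != (msg.group_id is not None):
            violations.append(
                f"message {msg.message_id!r}: group_id must be present iff kind is bct"
            )

    group_ids: set[str] = set()
    for g in lib.groups:
        if g.group_id in group_ids:
            violations.append(f"duplicate group_id {g.group_id!r}")
        group_ids.add(g.group_id)
        if not g.members:
            violations.append(f"group {g.group_id!r} ({g.label}) has no members")
        for m in g.members:
            if m.kind != "bct":
                violations.append(
                    f"group {g.group_id!r} member {m.message_id!r} has kind {m.kind!r}"
                )
            if m.group_id != g.group_id:
                violations.append(
                    f"message {m.message_id!r} group_id {m.group_id!r} does not "
                    f"match containing group {g.group_id!r}"
                )
    for m in lib.lifestyle:
        if m.kind != "lifestyle":
            violations.append(f"lifestyle list contains non-lifestyle {m.message_id!r}")
    for m in lib.control:
        if m.kind != "control":
            violations.append(f"control list contains non-control {m.message_id!r}")
    return violations


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _even_group_sizes(n: int, t: int) -> list[int]:
    """Distribute n messages over t groups as evenly as possible."""
    base, rem = divmod(n, t)
    return [base + 1 if i < rem else base for i in range(t)]


def generate_fixture_library(study: str, seed: int) -> MessageLibrary:
    """Build a synthetic library matching the study's published composition.

    Bodies are deterministic placeholder texts (a pure function of
    ``(study, seed)``); group labels follow the BCT taxonomy.  Pilot:
    157 BCT / 30 groups / 35 lifestyle / q=5.  Feasibility: 170 BCT /
    30 groups / 35 lifestyle / 6 control / q=2.
    """
    if study not in STUDY_COMPOSITION:
        raise LibraryError(f"unknown study {study!r}; expected one of {STUDIES}")
    n_bct, t, m, n_control, q = STUDY_COMPOSITION[study]
    rng = random.Random(f"{study}:{seed}")

    def body(prefix: str, detail: str) -> str:
        token = f"{rng.getrandbits(32):08x}"
        text = f"{prefix}: {detail} [{token}]"
        return text[:MAX_BODY_CHARS]

    groups: list[BCTGroup] = []
    sizes = _even_group_sizes(n_bct, t)
    for i, (label, size) in enumerate(zip(BCT_GROUP_LABELS, sizes), start=1):
        gid = f"g{i:02d}"
        members = [
            Message(
                message_id=f"bct-{gid}-{k:02d}",
                body=body(label, f"synthetic behaviour-change text {k}"),
                kind="bct",
                group_id=gid,
                study=study,
            )
            for k in range(1, size + 1)
        ]
        groups.append(BCTGroup(group_id=gid, label=label, members=members))

    lifestyle = [
        Message(
            message_id=f"life-{k:02d}",
            body=body("Lifestyle", f"synthetic general lifestyle advice {k}"),
            kind="lifestyle",
            study=study,
        )
        for k in range(1, m + 1)
    ]
    control = [
        Message(
            message_id=f"ctrl-{k}",
            body=body("Control", f"synthetic general-interest text {k}"),
            kind="control",
            study=study,
        )
        for k in range(1, n_control + 1)
    ]
    return MessageLibrary(
        study=study, groups=groups, lifestyle=lifestyle, control=control, interleave_q=q
    )


# ---------------------------------------------------------------------------
# File I/O — JSON (canonical) and flat CSV
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["message_id", "kind", "group_id", "group_label", "study", "body"]


def _library_to_dict(lib: MessageLibrary) -> dict:
    return {
        "study": lib.study,
        "interleave_q": lib.interleave_q,
        "groups": [
            {
                "group_id": g.group_id,
                "label": g.label,
                "members": [
                    {"message_id": m.message_id, "body": m.body, "study": m.study}
                    for m in g.members
                ],
            }
            for g in lib.groups
        ],
        "lifestyle": [
            {"message_id": m.message_id, "body": m.body, "study": m.study}
            for m in lib.lifestyle
        ],
        "control": [
            {"message_id": m.message_id, "body": m.body, "study": m.study}
            for m in lib.control
        ],
    }


def _library_from_dict(data: dict) -> MessageLibrary:
    groups = [
        BCTGroup(
            group_id=g["group_id"],
            label=g["label"],
            members=[
                Message(
                    message_id=m["message_id"],
                    body=m["body"],
                    kind="bct",
                    group_id=g["group_id"],
                    study=m.get("study", "both"),
                )
                for m in g["members"]
            ],
        )
        for g in data["groups"]
    ]
    mk = lambda m, kind: Message(  # noqa: E731
        message_id=m["message_id"], body=m["body"], kind=kind, study=m.get("study", "both")
    )
    return MessageLibrary(
        study=data["study"],
        groups=groups,
        lifestyle=[mk(m, "lifestyle") for m in data.get("lifestyle", [])],
        control=[mk(m, "control") for m in data.get("control", [])],
        interleave_q=int(data["interleave_q"]),
    )


def write_library(lib: MessageLibrary, path: str | Path, format: str | None = None) -> None:
    """Write a library to JSON (canonical) or flat CSV."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        path.write_text(json.dumps(_library_to_dict(lib), indent=1) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for g in lib.groups:
                for m in g.members:
                    writer.writerow(
                        {
                            "message_id": m.message_id,
                            "kind": "bct",
                            "group_id": g.group_id,
                            "group_label": g.label,
                            "study": m.study,
                            "body": m.body,
                        }
                    )
            for m in lib.lifestyle + lib.control:
                writer.writerow(
                    {
                        "message_id": m.message_id,
                        "kind": m.kind,
                        "group_id": "",
                        "group_label": "",
                        "study": m.study,
                        "body": m.body,
                    }
                )
    else:
        raise LibraryError(f"unknown format {fmt!r}")


def _rows_to_library(rows: Iterable[dict], study: str, interleave_q: int) -> MessageLibrary:
    groups: dict[str, BCTGroup] = {}
    lifestyle: list[Message] = []
    control: list[Message] = []
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        kind = (row.get("kind") or "").strip()
        if kind not in KINDS:
            raise LibraryError(f"record {i}: unknown kind {kind!r}")
        gid = (row.get("group_id") or "").strip() or None
        msg = Message(
            message_id=(row.get("message_id") or "").strip(),
            body=row.get("body") or "",
            kind=kind,
            group_id=gid if kind == "bct" else None,
            study=(row.get("study") or "both").strip(),
        )
        if kind == "bct":
            if gid is None:
                raise LibraryError(f"record {i}: bct message without group_id")
            grp = groups.setdefault(
                gid, BCTGroup(group_id=gid, label=(row.get("group_label") or gid).strip())
            )
            grp.members.append(msg)
        elif kind == "lifestyle":
            lifestyle.append(msg)
        else:
            control.append(msg)
    return MessageLibrary(
        study=study,
        groups=list(groups.values()),
        lifestyle=lifestyle,
        control=control,
        interleave_q=interleave_q,
    )


def load_library(
    path: str | Path,
    format: str | None = None,
    study: str | None = None,
    interleave_q: int | None = None,
) -> MessageLibrary:
    """Load and validate a library from JSON or flat CSV.

    The flat CSV carries no library-level header, so ``study`` (and
    optionally ``interleave_q``, defaulting to the study's standard value)
    must be supplied when reading CSV.

    Raises :class:`LibraryError` with full context on parse or validation
    failure; on validation failure every violation is listed.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise LibraryError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        try:
            lib = _library_from_dict(data)
        except (KeyError, TypeError) as exc:
            raise LibraryError(f"{path}: malformed library record: {exc}") from exc
    elif fmt == "csv":
        if study is None:
            raise LibraryError("reading CSV requires the study variant")
        q = interleave_q if interleave_q is not None else STUDY_COMPOSITION[study][4]
        with path.open(newline="") as fh:
            try:
                lib = _rows_to_library(csv.DictReader(fh), study, q)
            except csv.Error as exc:
                raise LibraryError(f"{path}: CSV parse error: {exc}") from exc
    else:
        raise LibraryError(f"unknown format {fmt!r}")

    violations = validate_library(lib)
    if violations:
        raise LibraryError(
            f"{path}: library failed validation with {len(violations)} violation(s):\n  "
            + "\n  ".join(violations)
        )
    return lib
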