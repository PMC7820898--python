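"""ANDL and DOT serialization of state-machine Petri nets.

ANDL (Abstract Net Description Language) is the plain-text net
description understood by the Snoopy/Charlie/Marcie Petri-net tool
family.  The dialect written here is the subset a single-token state
machine needs and round-trips through :func:`read_andl`::

    spn [<name>]
    {
    places:
    discrete:
    C0 = 1;
    C5 = 0;
    ...
    transitions:
    immediate:
    t_C0_C5
    : [C0 - 1] & [C5 + 1]
    : 3
    ;
    stochastic:
    t_C5_C7
    : [C5 - 1] & [C7 + 1]
    : 1
    ;
    }

Grammar notes: one ``spn`` block per file; every place is listed with
its initial marking (1 on C0, 0 elsewhere — the single token); every
transition names exactly one pre-arc ``[P - 1]`` and one post-arc
``[P + 1]``, both weight 1; the trailing number is the firing weight
(for immediate transitions, the observed initial-state multiplicity).
Whitespace and ``//`` comments are insignificant.

The DOT writer replaces interactive color editing: places are circles,
transitions are boxes, and the computed annotations (relative
frequency, relative stability, transit counts, provenance) are emitted
as plain node attributes for downstream styling.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import ParseError
from .petrinet import C0, StateNet, Transition

__all__ = ["write_andl", "read_andl", "write_dot", "export_net"]


def write_andl(net: StateNet, path: str | Path, name: str = "waddington") -> None:
    path = Path(path)
    lines = [f"spn [{name}]", "{", "places:", "discrete:"]
    lines.append(f"C{C0} = 1;")
    for p in sorted(net.places):
        lines.append(f"C{p} = 0;")
    lines.append("transitions:")
    immediates = sorted(net.immediate_transitions(), key=lambda t: t.post)
    if immediates:
        lines.append("immediate:")
        for t in immediates:
            lines.extend(_transition_block(t))
    lines.append("stochastic:")
    for t in sorted(net.ordinary_transitions(), key=lambda t: (t.pre, t.post)):
        lines.extend(_transition_block(t))
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _transition_block(t: Transition) -> list[str]:
    weight = int(t.weight) if float(t.weight).is_integer() else t.weight
    return [
        t.id,
        f": [C{t.pre} - 1] & [C{t.post} + 1]",
        f": {weight}",
        ";",
    ]


_PLACE_RE = re.compile(r"^C(\d+)\s*=\s*(\d+);$")
_ARCS_RE = re.compile(
    r"^:\s*\[C(\d+)\s*-\s*1\]\s*&\s*\[C(\d+)\s*\+\s*1\]$"
)
_WEIGHT_RE = re.compile(r"^:\s*([0-9.eE+-]+)$")


def read_andl(path: str | Path) -> StateNet:
    """Parse an ANDL file written by :func:`write_andl`."""
    path = Path(path)
    places: set[int] = set()
    marking: dict[int, int] = {}
    transitions: dict[tuple[int, int], Transition] = {}
    section = None
    mode = None  # immediate | stochastic
    pending: list[tuple[str, int]] = []

    def _flush(lineno: int) -> None:
        nonlocal pending
        if not pending:
            return
        if len(pending) != 3:
            raise ParseError(
                f"transition block has {len(pending)} clauses, expected 3", lineno
            )
        (name_line, name_no), (arcs_line, arcs_no), (weight_line, _) = pending
        arcs = _ARCS_RE.match(arcs_line)
        if not arcs:
            raise ParseError(f"bad arc clause {arcs_line!r}", arcs_no)
        pre, post = int(arcs.group(1)), int(arcs.group(2))
        w = _WEIGHT_RE.match(weight_line)
        if not w:
            raise ParseError(f"bad weight clause {weight_line!r}", arcs_no)
        immediate = mode == "immediate"
        transitions[(pre, post)] = Transition(
            pre, post, immediate=immediate, count=0, weight=float(w.group(1))
        )
        pending = []

    lineno = 0
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("//")[0].strip()
        if not line or line.startswith("spn") or line in ("{", "}"):
            continue
        if line in ("places:", "transitions:"):
            section = line[:-1]
            continue
        if section == "places" and line == "discrete:":
            continue
        if section == "transitions" and line in ("immediate:", "stochastic:"):
            _flush(lineno)
            mode = line[:-1]
            continue
        if section == "places":
            m = _PLACE_RE.match(line)
            if not m:
                raise ParseError(f"bad place declaration {line!r}", lineno)
            pid, tokens = int(m.group(1)), int(m.group(2))
            marking[pid] = tokens
            if pid != C0:
                places.add(pid)
            continue
        if section == "transitions":
            if line == ";":
                _flush(lineno)
                continue
            pending.append((line, lineno))
            continue
        raise ParseError(f"unexpected content {line!r}", lineno)
    _flush(lineno)  # trailing block, if the file omits a final section marker
    if marking.get(C0) != 1 or any(v != 0 for p, v in marking.items() if p != C0):
        raise ParseError("initial marking must be exactly one token on C0")
    # counts are annotation data, not part of ANDL; mirror weights for
    # transitions built with count-weights so structural equality holds
    for t in transitions.values():
        if float(t.weight).is_integer():
            t.count = int(t.weight)
    return StateNet(places=places, transitions=transitions)


def write_dot(net: StateNet, path: str | Path, name: str = "waddington") -> None:
    """Bipartite digraph in GraphViz DOT with annotations as attributes."""
    path = Path(path)
    ann = net.place_annotations
    lines = [f"digraph {name} {{", "  rankdir=TB;"]
    lines.append('  C0 [shape=circle, style=bold, label="C0", start="1"];')
    for p in sorted(net.places):
        attrs = [f'label="C{p}"', "shape=circle"]
        if ann is not None and p in ann.index:
            row = ann.loc[p]
            attrs.append(f'frequency="{row["relative_frequency"]:.6f}"')
            attrs.append(f'stability="{row["relative_stability"]:.6f}"')
            if bool(row["is_sink"]):
                attrs.append('terminal="1"')
            if bool(row["is_source"]):
                attrs.append('initial="1"')
        lines.append(f"  C{p} [{', '.join(attrs)}];")
    for (pre, post), t in sorted(net.transitions.items()):
        tid = t.id
        shape = "box" if not t.immediate else "box, style=filled, fillcolor=black"
        prov = ";".join(
            f"{e}:{c}" for e, c in sorted(t.provenance)
        )
        attrs = [f'label="{tid}"', f"shape={shape}", f'count="{t.count}"']
        if prov:
            attrs.append(f'provenance="{prov}"')
        lines.append(f"  {tid} [{', '.join(attrs)}];")
        lines.append(f"  C{pre} -> {tid};")
        lines.append(f"  {tid} -> C{post};")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_net(net: StateNet, fmt: str, path: str | Path) -> None:
    if fmt == "andl":
        write_andl(net, path)
    elif fmt == "dot":
        write_dot(net, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
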