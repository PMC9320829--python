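"""Backward-time demographic models for the structured coalescent.

A :class:`DemographicModel` describes a set of demes with haploid effective
sizes at the present, a time-ordered list of backward-time events (deme
joins, instantaneous resizes, migration-matrix switches) and a haploid
sample configuration.  Time is measured in generations, with 0 = present
and time increasing into the past.

Conventions
-----------
* All population sizes are **haploid** gene-copy counts; the pairwise
  coalescence rate inside a deme of size ``N`` is ``1/N`` per generation.
* Migration rates are **backward-in-time per-lineage** rates: ``m[i][j]``
  is the rate at which a lineage currently in deme ``i`` moves to deme
  ``j``.  Gene flow *forward in time* from deme A into deme B is therefore
  expressed as backward lineage movement B -> A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Join",
    "Resize",
    "SetMigration",
    "DemographicModel",
]


@dataclass(frozen=True)
class Join:
    """At ``time``, all lineages of ``source`` move into ``dest``; the
    source deme ceases to exist (backward in time)."""

    time: float
    source: str
    dest: str


@dataclass(frozen=True)
class Resize:
    """At ``time``, deme ``deme`` instantaneously takes haploid size ``size``."""

    time: float
    deme: str
    size: float


@dataclass(frozen=True)
class SetMigration:
    """At ``time``, the full backward migration matrix is replaced.

    ``rates`` maps ``(from_deme, to_deme)`` to a per-lineage per-generation
    rate; absent pairs are zero.
    """

    time: float
    rates: dict = field(default_factory=dict)


Event = Join | Resize | SetMigration


class DemographicModel:
    """Deme sizes plus time-ordered backward events and a sample layout.

    Parameters
    ----------
    demes
        List of ``(deme_id, haploid_size_at_present)`` pairs.
    events
        Events in non-decreasing time order (ties resolved by list order).
    sample_config
        Mapping ``deme_id -> haploid sample size``; demes omitted
        contribute no samples (e.g. ghost demes).
    migration
        Initial backward migration rates at time 0, as a
        ``(from, to) -> rate`` mapping.
    """

    def __init__(self, demes, events=(), sample_config=None, migration=None):
        self.demes = [(str(d), float(n)) for d, n in demes]
        self.deme_ids = [d for d, _ in self.demes]
        if len(set(self.deme_ids)) != len(self.deme_ids):
            raise ValueError("duplicate deme ids")
        self.events = list(events)
        self.sample_config = dict(sample_config or {})
        self.migration = {tuple(k): float(v) for k, v in (migration or {}).items()}
        self.validate()

    # -- validation -----------------------------------------------------

    def _index(self, deme: str) -> int:
        try:
            return self.deme_ids.index(deme)
        except ValueError:
            raise ValueError(f"unknown deme id {deme!r}") from None

    def validate(self) -> None:
        for d, n in self.demes:
            if not n > 0:
                raise ValueError(f"haploid size of deme {d!r} must be > 0, got {n}")
        for (a, b), r in self.migration.items():
            self._index(a), self._index(b)
            if a == b:
                raise ValueError("self-migration is not allowed")
            if r < 0:
                raise ValueError("migration rates must be >= 0")
        last_t = 0.0
        joined: set[str] = set()
        for ev in self.events:
            if ev.time < 0:
                raise ValueError("event times must be non-negative")
            if ev.time < last_t:
                raise ValueError(
                    f"events must be listed in non-decreasing time order "
                    f"(got {ev.time} after {last_t})"
                )
            last_t = ev.time
            if isinstance(ev, Join):
                self._index(ev.source), self._index(ev.dest)
                if ev.source in joined:
                    raise ValueError(f"deme {ev.source!r} joined twice")
                if ev.dest in joined:
                    raise ValueError(f"join destination {ev.dest!r} no longer exists")
                joined.add(ev.source)
            elif isinstance(ev, Resize):
                self._index(ev.deme)
                if not ev.size > 0:
                    raise ValueError("resize to non-positive size")
                if ev.deme in joined:
                    raise ValueError(f"resize of joined-away deme {ev.deme!r}")
            elif isinstance(ev, SetMigration):
                for (a, b), r in ev.rates.items():
                    self._index(a), self._index(b)
                    if r < 0:
                        raise ValueError("migration rates must be >= 0")
                    if r > 0 and (a in joined or b in joined):
                        raise ValueError(
                            f"migration involving joined-away deme "
                            f"({a!r} -> {b!r}) must be 0"
                        )
            else:  # pragma: no cover
                raise TypeError(f"unknown event type {type(ev)!r}")
        if len(self.demes) > 1 and len(joined) != len(self.demes) - 1:
            raise ValueError(
                "after the final join a single ancestral deme must remain"
            )
        for d, n in self.sample_config.items():
            self._index(d)
            if n < 0 or n != int(n):
                raise ValueError("sample sizes must be non-negative integers")

    # -- properties -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(sum(self.sample_config.values()))

    def sample_sizes(self) -> list[int]:
        """Haploid sample size per deme, in deme order."""
        return [int(self.sample_config.get(d, 0)) for d in self.deme_ids]

    # -- kernel encoding ------------------------------------------------

    def encode(self):
        """Flatten the model into the array form the simulation kernels use.

        Returns ``(sizes0, mig0, ev_time, ev_type, ev_a, ev_b, ev_size,
        mig_stack, samples)`` where event types are 0 = join, 1 = resize,
        2 = set-migration (``ev_a`` indexes ``mig_stack``).
        """
        D = len(self.demes)
        sizes0 = np.array([n for _, n in self.demes], dtype=np.float64)
        mig0 = np.zeros((D, D), dtype=np.float64)
        for (a, b), r in self.migration.items():
            mig0[self._index(a), self._index(b)] = r
        n_ev = len(self.events)
        ev_time = np.zeros(n_ev, dtype=np.float64)
        ev_type = np.zeros(n_ev, dtype=np.int64)
        ev_a = np.zeros(n_ev, dtype=np.int64)
        ev_b = np.zeros(n_ev, dtype=np.int64)
        ev_size = np.zeros(n_ev, dtype=np.float64)
        mats = []
        for k, ev in enumerate(self.events):
            ev_time[k] = ev.time
            if isinstance(ev, Join):
                ev_type[k] = 0
                ev_a[k] = self._index(ev.source)
                ev_b[k] = self._index(ev.dest)
            elif isinstance(ev, Resize):
                ev_type[k] = 1
                ev_a[k] = self._index(ev.deme)
                ev_size[k] = ev.size
            else:
                ev_type[k] = 2
                m = np.zeros((D, D), dtype=np.float64)
                for (a, b), r in ev.rates.items():
                    m[self._index(a), self._index(b)] = r
                ev_a[k] = len(mats)
                mats.append(m)
        mig_stack = (
            np.stack(mats) if mats else np.zeros((0, D, D), dtype=np.float64)
        )
        samples = np.array(self.sample_sizes(), dtype=np.int64)
        return sizes0, mig0, ev_time, ev_type, ev_a, ev_b, ev_size, mig_stack, samples

    # -- plain-text round trip ------------------------------------------

    def to_dict(self) -> dict:
        events = []
        for ev in self.events:
            if isinstance(ev, Join):
                events.append(
                    {"join": {"time": ev.time, "source": ev.source, "dest": ev.dest}}
                )
            elif isinstance(ev, Resize):
                events.append(
                    {"resize": {"time": ev.time, "deme": ev.deme, "size": ev.size}}
                )
            else:
                events.append(
                    {
                        "set_migration": {
                            "time": ev.time,
                            "rates": {f"{a}->{b}": r for (a, b), r in ev.rates.items()},
                        }
                    }
                )
        return {
            "demes": [{"id": d, "size": n} for d, n in self.demes],
            "migration": {f"{a}->{b}": r for (a, b), r in self.migration.items()},
            "events": events,
            "samples": dict(self.sample_config),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DemographicModel":
        def _pairs(d):
            out = {}
            for key, r in (d or {}).items():
                a, b = key.split("->")
                out[(a, b)] = float(r)
            return out

        events: list[Event] = []
        for item in data.get("events", []):
            (kind, body), = item.items()
            if kind == "join":
                events.append(Join(body["time"], body["source"], body["dest"]))
            elif kind == "resize":
                events.append(Resize(body["time"], body["deme"], body["size"]))
            elif kind == "set_migration":
                events.append(SetMigration(body["time"], _pairs(body.get("rates"))))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        return cls(
            demes=[(d["id"], d["size"]) for d in data["demes"]],
            events=events,
            sample_config=data.get("samples", {}),
            migration=_pairs(data.get("migration")),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DemographicModel":
        if isinstance(source, str) and "\n" not in source and source.endswith((".yml", ".yaml")):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls.from_dict(data)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DemographicModel(demes={self.demes}, n_events={len(self.events)}, "
            f"samples={self.sample_config})"
        )
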