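"""Name-based plugin registry for the analysis algorithms.

Five slots are open for extension: the replicate distance metric, the
two-sample statistical test, the KDE kernel, the replicate outlier rule and
the multiple-testing correction method.  Each slot ships a registered
default; registering a new implementation makes it immediately selectable
by name from configuration.  Third-party packages can also contribute via
the ``woundkit.plugins`` entry-point group.
"""

from __future__ import annotations

from typing import Callable

from .errors import ConflictError

SLOTS = (
    "distance_metric",
    "statistical_test",
    "kde_kernel",
    "outlier_rule",
    "correction_method",
)


class PluginRegistry:
    def __init__(self) -> None:
        self._slots: dict[str, dict[str, Callable]] = {s: {} for s in SLOTS}

    def register(self, slot: str, impl_name: str, implementation: Callable) -> "PluginRegistry":
        if slot not in self._slots:
            raise LookupError(f"unknown plugin slot {slot!r}; slots: {SLOTS}")
        if impl_name in self._slots[slot]:
            raise ConflictError(f"{impl_name!r} already registered in slot {slot!r}")
        self._slots[slot][impl_name] = implementation
        return self

    def get(self, slot: str, impl_name: str) -> Callable:
        if slot not in self._slots:
            raise LookupError(f"unknown plugin slot {slot!r}; slots: {SLOTS}")
        try:
            return self._slots[slot][impl_name]
        except KeyError:
            raise LookupError(
                f"no implementation {impl_name!r} in slot {slot!r}; "
                f"available: {sorted(self._slots[slot])}"
            ) from None

    def available(self, slot: str) -> list[str]:
        if slot not in self._slots:
            raise LookupError(f"unknown plugin slot {slot!r}")
        return sorted(self._slots[slot])

    def load_entry_points(self, group: str = "woundkit.plugins") -> None:
        """Discover third-party plugins declared as ``slot.name = callable``."""
        from importlib.metadata import entry_points

        for ep in entry_points(group=group):
            slot, _, impl_name = ep.name.partition(".")
            self.register(slot, impl_name, ep.load())


#: process-wide default registry; defaults are filled in by the modules
#: that own them (qc registers kernels/metrics, stats registers tests).
registry = PluginRegistry()


def register_plugin(slot: str, impl_name: str, implementation: Callable) -> PluginRegistry:
    return registry.register(slot, impl_name, implementation)


__all__ = ["SLOTS", "PluginRegistry", "registry", "register_plugin"]
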