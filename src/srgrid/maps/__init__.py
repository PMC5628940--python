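"""Bundled ASCII maze fixtures.

The full-scale mazes (``latent``, ``detour``, ``policy_reval``) are 10x10
grids topologically matching the revaluation-task layouts (start, reward(s),
barrier with an alternate corridor, distant second reward in the bottom-right
corner); the ``*_small`` variants preserve the same topology at reduced scale
for fast simulation. ``acquisition`` is the hallway maze used by the
acquisition-speed experiments (repeated trials from S to a rewarded R with
no preceding exploration phase).
"""

from importlib import resources

from ..gridworld import GridWorld, parse_grid_map

MAP_NAMES = (
    "latent", "detour", "policy_reval",
    "latent_small", "detour_small", "policy_reval_small",
    "acquisition",
)


def map_text(name: str) -> str:
    """Raw ASCII text of a bundled map."""
    if name not in MAP_NAMES:
        raise KeyError(f"unknown map {name!r}; known: {MAP_NAMES}")
    return (resources.files(__package__) / f"{name}.map").read_text()


def load_map(name: str) -> GridWorld:
    """Parse a bundled map into a :class:`GridWorld`."""
    return parse_grid_map(map_text(name))
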