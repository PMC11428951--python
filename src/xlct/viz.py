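"""Small plotting helpers: slice panels, line profiles, truth/recon overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import ProfileLine, normalize_volume


def save_slice_panel(volume: np.ndarray, path: str, title: str = "",
                     cmap: str = "inferno") -> None:
    """One panel per axial slice of the max-normalized volume."""
    vol = normalize_volume(np.asarray(volume, dtype=float))
    nz = vol.shape[0]
    fig, axes = plt.subplots(1, nz, figsize=(2.2 * nz, 2.6))
    axes = np.atleast_1d(axes)
    for z, ax in enumerate(axes):
        ax.imshow(vol[z], cmap=cmap, vmin=0, vmax=1, origin="lower")
        ax.set_title(f"z={z}", fontsize=8)
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_profile_plot(profiles: dict[str, ProfileLine], path: str,
                      title: str = "") -> None:
    """Overlayed normalized intensity profiles (e.g. methods side by side)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, prof in profiles.items():
        ax.plot(np.linspace(0, 1, len(prof.samples)), prof.samples, label=label)
    ax.set_xlabel("position along profile")
    ax.set_ylabel("normalized intensity")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_overlay(recon: np.ndarray, truth: np.ndarray, z: int, path: str) -> None:
    """Reconstruction slice with the true target outline overlaid."""
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.imshow(normalize_volume(recon)[z], cmap="inferno", vmin=0, vmax=1,
              origin="lower")
    ax.contour(np.asarray(truth)[z] > 0, levels=[0.5], colors="lime",
               linewidths=1.0)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
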