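"""Publication-style plots of fitted stability curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_stability_curves(fit_dir, out_path="stability_curves.png") -> Path:
    """Plot dG(T) per residue with grey +/- sigma bands.

    Reads ``stability_curves.tsv`` as written by the fit pipeline
    (residue_label, temperature_K, dG_kcal_mol, sigma_dG_kcal_mol).
    """
    table = pd.read_csv(Path(fit_dir) / "stability_curves.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in table.groupby("residue_label", sort=False):
        grp = grp.sort_values("temperature_K")
        ax.fill_between(grp.temperature_K,
                        grp.dG_kcal_mol - grp.sigma_dG_kcal_mol,
                        grp.dG_kcal_mol + grp.sigma_dG_kcal_mol,
                        color="0.8", lw=0)
        ax.plot(grp.temperature_K, grp.dG_kcal_mol, lw=1, label=str(label))
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("T (K)")
    ax.set_ylabel(r"$\Delta G$ (kcal/mol)")
    if table.residue_label.nunique() <= 12:
        ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
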