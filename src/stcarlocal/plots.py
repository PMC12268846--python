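"""Trace-plot export for visual convergence checking."""

from __future__ import annotations

from pathlib import Path

from .model import PosteriorSamples


def trace_plots(
    samples: PosteriorSamples,
    out: str | Path,
    names: list[str] | None = None,
    ncols: int = 2,
) -> Path:
    """Write trace plots of monitored scalar chains to one figure file.

    ``names`` defaults to every monitored scalar (betas, lambdas,
    hyperparameters).  The file format follows the suffix of ``out``
    (png, pdf, svg).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chains = samples.scalar_chains()
    if names is not None:
        chains = {k: chains[k] for k in names}
    n = len(chains)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(5 * ncols, 1.8 * nrows), squeeze=False
    )
    for ax, (nm, ch) in zip(axes.ravel(), chains.items()):
        ax.plot(ch, lw=0.4)
        ax.set_ylabel(nm, fontsize=8)
        ax.tick_params(labelsize=7)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
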