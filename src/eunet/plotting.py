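"""Loss-curve plotting for training results."""

from __future__ import annotations

from pathlib import Path


def plot_loss(result, path, title: str = "Segmentation loss") -> None:
    """Plot per-epoch training (and validation, if present) Dice loss.

    ``result`` is a :class:`~eunet.model.TrainingResult`.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = range(1, result.epochs_run + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(epochs, result.train_loss, label="train (batch mean)")
    ax.plot(epochs, result.train_eval_loss, label="train (eval mode)")
    if any(v is not None for v in result.val_loss):
        ax.plot(epochs, [v for v in result.val_loss], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("Dice loss")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
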