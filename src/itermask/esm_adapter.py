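"""Adapter hook for a pretrained MSA-conditioned masked language model.

Wraps the ``fair-esm`` MSA Transformer behind the package's
masked-sequence-model contract (masked :class:`~itermask.msa.Msa` in,
M x L x q logits out) so that the generation pipeline can run against real
pretrained weights when they are installed and downloaded. ``fair-esm``
and ``torch`` are deliberately not dependencies of this package; this
module imports them lazily and fails with a clear message otherwise. The
adapter is untested in the default suite, which exercises the pipeline
through the exact Potts-conditional oracle instead.
"""

from __future__ import annotations

import numpy as np

from .msa import Msa


class EsmMsaAdapter:
    """Masked-sequence model backed by the fair-esm MSA Transformer."""

    def __init__(self, model_name: str = "esm_msa1b_t12_100M_UR50S"):
        try:
            import esm  # type: ignore
            import torch  # noqa: F401
        except ImportError as err:  # pragma: no cover - optional dependency
            raise ImportError(
                "the esm adapter requires the optional packages 'fair-esm' and "
                "'torch'; install them and download the pretrained weights to "
                "use a real masked language model") from err
        self._model, self._esm_alphabet = getattr(
            esm.pretrained, model_name)()
        self._model.eval()
        self._batch_converter = self._esm_alphabet.get_batch_converter()

    def __call__(self, masked: Msa) -> np.ndarray:  # pragma: no cover
        import torch

        mask_tok = self._esm_alphabet.mask_idx
        seqs = []
        for k, row in enumerate(masked.data):
            chars = [("<mask>" if s == masked.alphabet.mask_index
                      else masked.alphabet.symbols[s]) for s in row]
            seqs.append((masked.ids[k], "".join(
                c if c != "<mask>" else "-" for c in chars)))
        _, _, tokens = self._batch_converter([seqs])
        for k, row in enumerate(masked.data):
            for i, s in enumerate(row):
                if s == masked.alphabet.mask_index:
                    tokens[0, k, i + 1] = mask_tok  # +1 for BOS column
        with torch.no_grad():
            out = self._model(tokens)["logits"][0]
        # map esm vocabulary back onto the package alphabet
        idx = [self._esm_alphabet.get_idx(c) for c in masked.alphabet.symbols]
        logits = out[:, 1:, :][:, :, idx]
        return logits.cpu().numpy()
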