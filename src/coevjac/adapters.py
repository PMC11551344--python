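"""Adapters exposing external pretrained sequence models as LogitModels.

An external masked language model typically (a) frames sequences with
begin/end-of-sequence tokens and (b) orders its vocabulary differently from
the 20-letter residue alphabet.  :class:`ExternalLogitAdapter` does the
bookkeeping once so every downstream computation sees the plain (L, 20)
contract: our position i is model position i + 1, and logit columns come
back in our residue order.

For masked-context experiments the BOS/EOS slots can be filled with the
model's mask token instead, hiding the terminus signal from the model.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np

from .alphabet import MASK_INDEX, Alphabet
from .models import ModelContractError

__all__ = ["ExternalLogitAdapter", "esm2_logit_model"]


class ExternalLogitAdapter:
    """Wrap ``forward(token_ids) -> (L+2, V) logits`` behind the LogitModel contract.

    Parameters
    ----------
    forward:
        Callable taking a 1-D array of external token ids (with BOS/EOS
        framing) and returning per-position logits over the external
        vocabulary ``V``, including the framing positions.
    vocab:
        Mapping from token string (single residue letters plus ``"<mask>"``,
        ``"<bos>"``, ``"<eos>"``) to external id.  Every residue of the
        alphabet and the three specials must be present.
    replace_bos_eos_with_mask:
        Present the mask id in the framing slots instead of BOS/EOS — the
        convention used by the masked contact-recovery experiments.
    """

    supports_soft = False

    def __init__(
        self,
        forward: Callable[[np.ndarray], np.ndarray],
        vocab: Mapping[str, int],
        alphabet: Alphabet | None = None,
        replace_bos_eos_with_mask: bool = False,
    ):
        self.forward = forward
        self.alphabet = alphabet or Alphabet()
        missing = [t for t in self.alphabet.tokens if t not in vocab]
        for special in ("<mask>", "<bos>", "<eos>"):
            if special not in vocab:
                missing.append(special)
        if missing:
            raise KeyError(f"external vocabulary lacks tokens: {missing}")
        self._residue_ids = np.array(
            [vocab[t] for t in self.alphabet.tokens], dtype=np.int64
        )
        self._mask_id = vocab["<mask>"]
        self._bos_id = vocab["<mask>" if replace_bos_eos_with_mask else "<bos>"]
        self._eos_id = vocab["<mask>" if replace_bos_eos_with_mask else "<eos>"]

    def evaluate(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.asarray(tokens, dtype=np.int64)
        L = tokens.size
        ext = np.empty(L + 2, dtype=np.int64)
        ext[0] = self._bos_id
        ext[-1] = self._eos_id
        body = np.where(
            tokens == MASK_INDEX, self._mask_id, self._residue_ids[np.clip(tokens, 0, None)]
        )
        ext[1:-1] = body
        logits = np.asarray(self.forward(ext), dtype=np.float64)
        if logits.ndim != 2 or logits.shape[0] != L + 2:
            raise ModelContractError(
                f"external model returned shape {logits.shape}, expected ({L + 2}, V)"
            )
        # strip framing rows, reorder columns into our residue order
        return logits[1:-1][:, self._residue_ids]

    def evaluate_soft(self, distribution: np.ndarray) -> np.ndarray:
        raise NotImplementedError("external adapters expose categorical inputs only")


def esm2_logit_model(model_name: str = "esm2_t36_3B_UR50D", **kwargs) -> ExternalLogitAdapter:
    """Adapter around a pretrained ESM-2 model (requires torch + fair-esm).

    Provided for users with the optional dependencies installed; the package
    itself never needs pretrained weights.
    """
    try:
        import torch  # noqa: F401
        import esm
    except ImportError as exc:
        raise ImportError(
            "the ESM-2 adapter needs the optional dependencies 'torch' and "
            "'fair-esm'; install them or use the fixture models instead"
        ) from exc

    import torch

    model, esm_alphabet = esm.pretrained.load_model_and_alphabet(model_name)
    model.eval()

    def forward(token_ids: np.ndarray) -> np.ndarray:
        with torch.no_grad():
            out = model(torch.as_tensor(token_ids[None], dtype=torch.long))
        return out["logits"][0].cpu().numpy()

    vocab = {t: esm_alphabet.get_idx(t) for t in Alphabet().tokens}
    vocab["<mask>"] = esm_alphabet.mask_idx
    vocab["<bos>"] = esm_alphabet.cls_idx
    vocab["<eos>"] = esm_alphabet.eos_idx
    return ExternalLogitAdapter(forward, vocab, **kwargs)
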