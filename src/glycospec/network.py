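"""The glycopeptide fragment-spectrum prediction network.

Architecture (hidden size h, defaults h=256, dropout 0.25):

* peptide encoder: per-residue one-hot (20) + PTM elemental vector (6) into
  two stacked bidirectional LSTM layers;
* glycan encoder: per-node monosaccharide one-hot (5) into a child-sum tree
  LSTM traversed bottom-up (branch order is ignored by construction);
* cross-moiety fusion: the glycan root state is added to the peptide feature
  at the glycosite; the peptide final state is added back to the root node;
  a learned 2-d charge embedding is concatenated on both sides;
* peptide head: two further bidirectional LSTM layers, then a dense + ReLU
  producing 4 intensities per backbone cleavage (b/y ions at 1+/2+);
* glycan head: a second, top-down tree LSTM; per glycosidic cleavage the
  lost-node and retained-node features are attention-pooled and concatenated
  into a 2h-wide cleavage vector; each structure-specific fragment aggregates
  its boundary cleavages with an LSTM + attention and a dense + ReLU emits Y
  intensities at 1+..3+ (and B intensities at 1+ when enabled); intensities
  of isomeric fragments are summed per composition;
* ratio head: attention-pooled peptide and glycan features, dense + sigmoid,
  predicting the peptide fraction r of total fragment intensity; the peptide
  part is scaled to r and the glycan part to 1-r in the assembled spectrum.

At the default sizes the model carries ~7M parameters (~5M peptide-side,
~2M glycan-side).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .fragments import FragmentIndex, GlycopeptidePrecursor, StructureFragment
from .glycans import GlycanTree
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import AttentionPool, BiLSTMStack, ChildSumTreeLSTM, Dense, LSTM
from .peptides import AMINO_ACIDS

__all__ = ["ModelConfig", "PredictedSpectrum", "GlycoSpectrumNetwork"]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MONO_ORDER = "HNAGF"  # one-hot channel order: Hex, HexNAc, NeuAc, NeuGc, Fuc
_MONO_INDEX = {c: i for i, c in enumerate(_MONO_ORDER)}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; the defaults reproduce the reference sizes."""

    hidden_size: int = 256
    dropout: float = 0.25
    peptide_lstm_layers: tuple[int, int] = (2, 2)
    charge_embed_dim: int = 2
    peptide_out_dims: int = 4
    y_out_dims: int = 3
    b_out_dims: int = 1
    with_B: bool = False
    max_charge: int = 6

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["peptide_lstm_layers"] = tuple(d["peptide_lstm_layers"])
        return cls(**d)


@dataclass
class PredictedSpectrum:
    """Assembled model output for one precursor."""

    index: FragmentIndex
    pep: np.ndarray  # (4*(L-1),) raw peptide-channel intensities
    y: np.ndarray  # (3*n_Y_comps,) composition-level Y intensities
    b: np.ndarray  # (n_B_comps,)
    ratio: float
    full: np.ndarray  # assembled spectrum, sums to 1
    structure_y: dict[frozenset, np.ndarray] = field(default_factory=dict)
    structure_b: dict[frozenset, np.ndarray] = field(default_factory=dict)
    cleavage_attention: dict = field(default_factory=dict)
    fragment_attention: dict = field(default_factory=dict)

    def glycan_vector(self) -> np.ndarray:
        return np.concatenate([self.y, self.b])


def _peptide_features(precursor: GlycopeptidePrecursor) -> np.ndarray:
    pep = precursor.peptide
    L = len(pep)
    x = np.zeros((L, 26))
    for i, aa in enumerate(pep.sequence):
        x[i, _AA_INDEX[aa]] = 1.0
    for pos, mod in pep.modifications.items():
        x[pos, 20:26] = mod.elements
    return x


def _glycan_features(tree: GlycanTree) -> np.ndarray:
    x = np.zeros((tree.n_nodes, 5))
    for v, code in enumerate(tree.codes):
        x[v, _MONO_INDEX[code]] = 1.0
    return x


def _bottom_up_order(tree: GlycanTree) -> list[int]:
    order = sorted(range(tree.n_nodes), key=tree.depth, reverse=True)
    return order


def _top_down_order(tree: GlycanTree) -> list[int]:
    return sorted(range(tree.n_nodes), key=tree.depth)


class GlycoSpectrumNetwork:
    """The spectrum predictor; parameters are plain named tensors."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden_size
        ce = config.charge_embed_dim
        self.pep_lstm1 = BiLSTMStack(rng, 26, h, config.peptide_lstm_layers[0])
        self.glycan_bu = ChildSumTreeLSTM(rng, 5, h)
        self.fuse_g2p = Dense(rng, h, 2 * h)
        self.charge_embed = Tensor(
            rng.uniform(-0.5, 0.5, size=(config.max_charge, ce))
        )
        self.pep_lstm2 = BiLSTMStack(
            rng, 2 * h + ce, h, config.peptide_lstm_layers[1]
        )
        self.pep_head = Dense(rng, 4 * h, config.peptide_out_dims)
        self.fuse_p2g = Dense(rng, 2 * h, h)
        self.glycan_td = ChildSumTreeLSTM(rng, 5 + h + ce, h)
        self.attn_lost = AttentionPool(rng, h)
        self.attn_retained = AttentionPool(rng, h)
        self.frag_lstm = LSTM(rng, 2 * h, h)
        self.frag_attn = AttentionPool(rng, h)
        self.y_head = Dense(rng, h, config.y_out_dims)
        self.b_head = Dense(rng, h, config.b_out_dims) if config.with_B else None
        self.ratio_attn_pep = AttentionPool(rng, 2 * h)
        self.ratio_attn_gly = AttentionPool(rng, h)
        self.ratio_head = Dense(rng, 3 * h, 1)

    # ------------------------------------------------------------------ params
    def params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.pep_lstm1.params("pep_lstm1"))
        out.update(self.glycan_bu.params("glycan_bu"))
        out.update(self.fuse_g2p.params("fuse_g2p"))
        out["charge_embed"] = self.charge_embed
        out.update(self.pep_lstm2.params("pep_lstm2"))
        out.update(self.pep_head.params("pep_head"))
        out.update(self.fuse_p2g.params("fuse_p2g"))
        out.update(self.glycan_td.params("glycan_td"))
        out.update(self.attn_lost.params("attn_lost"))
        out.update(self.attn_retained.params("attn_retained"))
        out.update(self.frag_lstm.params("frag_lstm"))
        out.update(self.frag_attn.params("frag_attn"))
        out.update(self.y_head.params("y_head"))
        if self.b_head is not None:
            out.update(self.b_head.params("b_head"))
        out.update(self.ratio_attn_pep.params("ratio_attn_pep"))
        out.update(self.ratio_attn_gly.params("ratio_attn_gly"))
        out.update(self.ratio_head.params("ratio_head"))
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params().values())

    def peptide_encoder_param_names(self) -> set[str]:
        """The first two BiLSTM layers (frozen during transfer learning)."""
        return {k for k in self.params() if k.startswith("pep_lstm1")}

    def non_b_param_names(self) -> set[str]:
        """Everything but the B head (frozen while training the B model)."""
        return {k for k in self.params() if not k.startswith("b_head")}

    # ----------------------------------------------------------------- forward
    def forward_tensors(
        self,
        index: FragmentIndex,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Run the network; returns tensors for the loss plus ndarray extras."""
        cfg = self.config
        precursor = index.precursor
        if not 1 <= precursor.charge <= cfg.max_charge:
            raise ValueError(
                f"unsupported precursor charge {precursor.charge} "
                f"(1..{cfg.max_charge})"
            )
        if training and rng is None:
            rng = np.random.default_rng()
        drop = cfg.dropout if training else 0.0

        pep = precursor.peptide
        tree = precursor.glycan
        L = len(pep)
        n = tree.n_nodes

        # peptide encoder
        x_pep = Tensor(_peptide_features(precursor))
        pep1, pep1_final = self.pep_lstm1.run(x_pep)
        if drop > 0:
            pep1 = ag.dropout(pep1, drop, rng)

        # glycan bottom-up encoder
        x_gly = Tensor(_glycan_features(tree))
        bu = self.glycan_bu.run(
            x_gly,
            _bottom_up_order(tree),
            {v: list(tree.children[v]) for v in range(n)},
        )
        if drop > 0:
            bu = ag.dropout(bu, drop, rng)

        # fusion: glycan root -> glycosite; charge embedding at each position
        root_feat = ag.rows(bu, [tree.root])
        pep_fused = ag.index_add_row(
            pep1, pep.glycosite, self.fuse_g2p(root_feat)
        )
        ce_row = ag.rows(self.charge_embed, [precursor.charge - 1])
        ones_L = Tensor(np.ones((L, 1)))
        pep2_in = ag.concat_cols([pep_fused, ag.matmul(ones_L, ce_row)])
        pep2, _ = self.pep_lstm2.run(pep2_in)
        if drop > 0:
            pep2 = ag.dropout(pep2, drop, rng)

        # peptide head: adjacent-position features per backbone cleavage
        left = ag.rows(pep2, list(range(L - 1)))
        right = ag.rows(pep2, list(range(1, L)))
        pep_mat = ag.relu(self.pep_head(ag.concat_cols([left, right])))
        pep_flat = ag.reshape(pep_mat, (-1,))

        # glycan top-down encoder
        bu_updated = ag.index_add_row(bu, tree.root, self.fuse_p2g(pep1_final))
        ones_n = Tensor(np.ones((n, 1)))
        td_in = ag.concat_cols([x_gly, bu_updated, ag.matmul(ones_n, ce_row)])
        td = self.glycan_td.run(
            td_in,
            _top_down_order(tree),
            {v: [tree.parent[v]] for v in range(n) if tree.parent[v] >= 0},
        )
        if drop > 0:
            td = ag.dropout(td, drop, rng)

        # per-cleavage features: attention over lost and retained node sets
        h = cfg.hidden_size
        zero_h = Tensor(np.zeros((1, h)))
        cleav_vec: dict = {}
        cleav_attn: dict = {}
        all_sites: dict = {}
        for f in index.y_structures + index.b_structures:
            for s in f.cleavages:
                all_sites[s.edge] = s
        for edge, s in all_sites.items():
            lost = sorted(s.lost_ids)
            pooled_lost, w_lost = self.attn_lost(ag.rows(td, lost))
            if s.retained_ids:
                ret = sorted(s.retained_ids)
                pooled_ret, w_ret = self.attn_retained(ag.rows(td, ret))
            else:
                pooled_ret, w_ret = zero_h, np.zeros(0)
            cleav_vec[edge] = ag.concat_cols([pooled_lost, pooled_ret])
            cleav_attn[edge] = {"lost": w_lost, "retained": w_ret}

        def aggregate(frags: Sequence[StructureFragment], head: Dense):
            """Batched LSTM+attention aggregation over boundary cleavages."""
            if not frags:
                return None, {}, {}
            seqs = []
            for f in frags:
                edges = [s.edge for s in f.cleavages]
                if training:
                    edges = [edges[i] for i in rng.permutation(len(edges))]
                seqs.append(edges)
            by_k: dict[int, list[int]] = {}
            for i, s in enumerate(seqs):
                by_k.setdefault(len(s), []).append(i)
            pieces = []
            positions: list[int] = []
            frag_attn_w: dict = {}
            for k, members in sorted(by_k.items()):
                step_inputs = [
                    ag.concat_rows([cleav_vec[seqs[i][t]] for i in members])
                    for t in range(k)
                ]
                outs, _ = self.frag_lstm.run_batch_steps(step_inputs)
                scores = ag.concat_cols(
                    [self.frag_attn.score(o) for o in outs]
                )
                w = ag.softmax_rows1(scores)
                pooled = ag.mul(ag.cols(w, 0, 1), outs[0])
                for t in range(1, k):
                    pooled = ag.add(
                        pooled, ag.mul(ag.cols(w, t, t + 1), outs[t])
                    )
                pieces.append(ag.relu(head(pooled)))
                positions.extend(members)
                for row, i in enumerate(members):
                    frag_attn_w[frags[i].retained_ids] = dict(
                        zip(seqs[i], w.data[row].copy())
                    )
            stacked = ag.concat_rows(pieces)
            # permutation mapping concatenated rows back to fragment order
            perm = np.zeros(len(frags), dtype=int)
            for row, i in enumerate(positions):
                perm[i] = row
            return stacked, perm, frag_attn_w

        y_struct, y_perm, y_attn = aggregate(index.y_structures, self.y_head)
        # composition-level Y intensities: sum members per composition
        pos_of = {
            f.retained_ids: y_perm[i]
            for i, f in enumerate(index.y_structures)
        }
        M = np.zeros((index.n_y_comps, len(index.y_structures)))
        for ci, (_comp, members) in enumerate(index.y_groups):
            for m in members:
                M[ci, pos_of[m.retained_ids]] = 1.0
        y_comp = ag.matmul(Tensor(M), y_struct)  # (n_comps, 3)
        y_flat = ag.reshape(y_comp, (-1,))

        b_flat = None
        b_attn: dict = {}
        b_struct = None
        b_perm = None
        if self.b_head is not None and index.b_structures:
            b_struct, b_perm, b_attn = aggregate(index.b_structures, self.b_head)
            pos_b = {
                f.retained_ids: b_perm[i]
                for i, f in enumerate(index.b_structures)
            }
            Mb = np.zeros((index.n_b, len(index.b_structures)))
            for ci, (_comp, members) in enumerate(index.b_groups):
                for m in members:
                    Mb[ci, pos_b[m.retained_ids]] = 1.0
            b_flat = ag.reshape(ag.matmul(Tensor(Mb), b_struct), (-1,))

        # ratio head
        pooled_pep, _ = self.ratio_attn_pep(pep2)
        pooled_gly, _ = self.ratio_attn_gly(td)
        r = ag.sigmoid(self.ratio_head(ag.concat_cols([pooled_pep, pooled_gly])))
        r_scalar = ag.reshape(r, ())

        # assemble: peptide part scaled to r, glycan part (Y + B) to 1 - r
        if b_flat is not None:
            gly_flat = ag.concat_rows([y_flat, b_flat])
        else:
            gly_flat = y_flat
        s_pep = ag.sum_all(pep_flat)
        s_gly = ag.sum_all(gly_flat)
        parts = []
        if s_pep.data > 0:
            parts.append(ag.mul(pep_flat, ag.div(r_scalar, s_pep)))
        else:
            parts.append(pep_flat)
        if s_gly.data > 0:
            parts.append(
                ag.mul(gly_flat, ag.div(ag.rsub_const(1.0, r_scalar), s_gly))
            )
        else:
            parts.append(gly_flat)
        full = ag.concat_rows(parts)

        return {
            "pep": pep_flat,
            "y": y_flat,
            "b": b_flat,
            "ratio": r_scalar,
            "full": full,
            "y_struct": y_struct,
            "y_perm": y_perm,
            "b_struct": b_struct,
            "b_perm": b_perm,
            "y_attn": y_attn,
            "b_attn": b_attn,
            "cleav_attn": cleav_attn,
        }

    def predict(self, index: FragmentIndex) -> PredictedSpectrum:
        """Deterministic evaluation-mode forward pass."""
        out = self.forward_tensors(index, training=False)
        structure_y = {
            f.retained_ids: out["y_struct"].data[out["y_perm"][i]].copy()
            for i, f in enumerate(index.y_structures)
        }
        structure_b = {}
        if out["b_struct"] is not None:
            structure_b = {
                f.retained_ids: out["b_struct"].data[out["b_perm"][i]].copy()
                for i, f in enumerate(index.b_structures)
            }
        b = (
            out["b"].data.copy()
            if out["b"] is not None
            else np.zeros(index.n_b)
        )
        return PredictedSpectrum(
            index=index,
            pep=out["pep"].data.copy(),
            y=out["y"].data.copy(),
            b=b,
            ratio=float(out["ratio"].data),
            full=out["full"].data.copy(),
            structure_y=structure_y,
            structure_b=structure_b,
            cleavage_attention=out["cleav_attn"],
            fragment_attention={"Y": out["y_attn"], "B": out["b_attn"]},
        )

    def predict_precursor(
        self, precursor: GlycopeptidePrecursor
    ) -> PredictedSpectrum:
        return self.predict(
            FragmentIndex(precursor, with_B=self.config.with_B)
        )

    # -------------------------------------------------------------- checkpoint
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in params.items():
            p.data = np.array(state[k], dtype=np.float64)

    def save(self, path: str) -> None:
        if not path.endswith(".npz"):
            path += ".npz"
        np.savez(
            path,
            __config__=np.frombuffer(
                self.config.to_json().encode(), dtype=np.uint8
            ),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str) -> "GlycoSpectrumNetwork":
        with np.load(path) as data:
            config = ModelConfig.from_json(
                bytes(data["__config__"].tobytes()).decode()
            )
            net = cls(config)
            net.load_state_dict(
                {k: data[k] for k in data.files if k != "__config__"}
            )
        return net
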