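"""Human-feedback channels and the human-feedback (HF) policy.

Every observed robot action yields one binary feedback label through one of
four channels:

``oracle``      the simulated human agrees with the A* green arrow exactly;
``noisy``       the oracle label flipped independently with probability
                ``flip_prob`` (e.g. 0.3 -> 70%-accurate keyboard feedback);
``bci_sim``     the oracle label passed through a 2x2 confusion channel with
                configurable per-class correct-decision probabilities — a
                surrogate for an EEG decoder of stated quality;
``bci_full``    the full loop: a synthetic EEG epoch is generated
                conditioned on the action's true correctness, preprocessed,
                and classified by a calibrated CNN; the predicted class is
                the label.

The HF policy is a small network (8 inputs -> 32 rectified units -> 6
outputs -> softmax) trained online: each output is the probability that the
corresponding action receives positive feedback.  The replay store keeps
every past feedback event (append-only) and mini-batches are stratified to
10% collision / 90% non-collision samples when enough collisions exist —
the only prioritization applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.stats import norm

from .gridworld import (GridWorld, GridState, N_ACTIONS, optimal_action)
from .nn import MLP, Adam, softmax

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeedbackEvent:
    """One observed robot action with its delivered binary feedback."""

    state: GridState
    action: int
    optimal: int
    label: bool            # True = positive feedback ("correct action")
    source: str            # oracle | noisy | bci_sim | bci_full
    collision: bool = False

    def __post_init__(self):
        if self.source == "oracle" and self.label != (self.action == self.optimal):
            raise ValueError("oracle label must equal (action == optimal)")


# ------------------------------------------------------------- channels

def oracle_feedback(state: GridState, action: int, optimal: int,
                    collision: bool = False) -> FeedbackEvent:
    """Perfect explicit feedback: positive iff the action matches the
    green arrow (A* optimal action)."""
    return FeedbackEvent(state=state, action=action, optimal=optimal,
                         label=(action == optimal), source="oracle",
                         collision=collision)


def noisy_feedback(event: FeedbackEvent, flip_prob: float,
                   rng: np.random.Generator) -> FeedbackEvent:
    """Flip the label independently with probability ``flip_prob``."""
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError("flip_prob must lie in [0, 1]")
    label = event.label
    if rng.random() < flip_prob:
        label = not label
    return _dc_replace(event, label=label, source="noisy")


def bci_sim_feedback(event: FeedbackEvent, accuracy_spec: tuple,
                     rng: np.random.Generator) -> FeedbackEvent:
    """Pass the oracle label through a 2x2 confusion channel.

    ``accuracy_spec = (p_correct_given_positive, p_correct_given_negative)``:
    the probability that a truly positive (resp. negative) label is delivered
    unchanged.  (1, 1) is the oracle; (0.5, 0.5) is chance.
    """
    p_pos, p_neg = accuracy_spec
    for p in (p_pos, p_neg):
        if not (0.0 <= p <= 1.0):
            raise ValueError("accuracy probabilities must lie in [0, 1]")
    keep = p_pos if event.label else p_neg
    label = event.label if rng.random() < keep else not event.label
    return _dc_replace(event, label=label, source="bci_sim")


def accuracy_from_auc(auc: float) -> float:
    """Map a decoder ROC-AUC to a balanced decision accuracy.

    Under the equal-variance binormal model, AUC = Phi(d'/sqrt(2)) and the
    accuracy at the optimal (0.5) threshold with balanced classes is
    Phi(d'/2), i.e. Phi(Phi^-1(AUC)/sqrt(2)).  A documented modelling
    assumption; the realized accuracy should be reported next to the AUC,
    not equated with it.
    """
    if not (0.0 < auc < 1.0):
        raise ValueError("AUC must lie strictly in (0, 1)")
    return float(norm.cdf(norm.ppf(auc) / np.sqrt(2.0)))


class BCIFullChannel:
    """End-to-end implicit feedback: synthesize EEG -> preprocess -> classify.

    For each observed action, one synthetic epoch is generated conditioned on
    the action's true correctness (error-related template present iff the
    action was wrong), preprocessed with the standard chain, cut to the
    interest window, and classified by the calibrated CNN.  The predicted
    class becomes the feedback label.
    """

    def __init__(self, classifier, montage, errp, preproc_cfg=None):
        from .preprocess import PreprocConfig
        self.classifier = classifier
        self.montage = montage
        self.errp = errp
        self.preproc_cfg = preproc_cfg or PreprocConfig()
        if getattr(classifier.cfg, "n_channels", None) != montage.n_channels:
            raise ValueError("classifier channel count does not match montage")

    def __call__(self, event: FeedbackEvent,
                 rng: np.random.Generator) -> FeedbackEvent:
        from .preprocess import extract_interest_window, preprocess_recording
        from .simulate import generate_recording

        is_error = event.action != event.optimal
        seed = int(rng.integers(2 ** 31))
        rec = generate_recording(self.montage, self.errp, n_trials=1,
                                 error_fraction=0.0,
                                 inter_trial_interval=2.0, seed=seed,
                                 error_flags=np.array([is_error]))
        epochs = extract_interest_window(
            preprocess_recording(rec, self.preproc_cfg), self.preproc_cfg)
        p_error = float(self.classifier.decision_function(epochs.data)[0])
        # predicted "error" means negative feedback
        label = p_error < 0.5
        return _dc_replace(event, label=bool(label), source="bci_full")


def make_channel(spec: str, seed: int = 0, **kwargs):
    """Build a feedback channel callable ``(event, rng) -> FeedbackEvent``.

    ``spec``: ``oracle``, ``noisy:P``, ``bci-sim:AUC`` or ``bci-full``
    (the latter requires classifier/montage/errp kwargs).
    """
    if spec == "oracle":
        return lambda event, rng: event
    if spec.startswith("noisy"):
        p = float(spec.split(":")[1]) if ":" in spec else 0.3
        return lambda event, rng: noisy_feedback(event, p, rng)
    if spec.startswith("bci-sim") or spec.startswith("bci_sim"):
        auc = float(spec.split(":")[1]) if ":" in spec else 0.77
        acc = accuracy_from_auc(auc)
        return lambda event, rng: bci_sim_feedback(event, (acc, acc), rng)
    if spec in ("bci-full", "bci_full"):
        return BCIFullChannel(**kwargs)
    raise ValueError(f"unknown feedback channel '{spec}'")


# ------------------------------------------------------------ HF policy

@dataclass(frozen=True)
class HFConfig:
    """HF-policy training knobs (network shape fixed by the protocol)."""

    hidden: int = 32
    lr: float = 1e-3
    batch_size: int = 20
    collision_fraction: float = 0.10
    n_labels: int = 1000
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    updates_per_event: int = 8
    action_selection: str = "epsilon_greedy"   # or "random"
    loss: str = "executed_bce"                 # or "one_vs_all_bce"


class HFPolicy:
    """8 -> 32 (ReLU) -> 6 -> softmax network over actions.

    ``predict_proba(obs)`` returns a length-6 probability vector: the
    (normalized) probability that each action would receive positive
    feedback at that observation.  The replay store is append-only.
    """

    def __init__(self, cfg: HFConfig = HFConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.net = MLP([8, cfg.hidden, N_ACTIONS], rng, head="softmax")
        self.opt = Adam(self.net.params(), lr=cfg.lr)
        self.replay: list = []          # append-only FeedbackEvent store
        self._collision_idx: list = []
        self._noncollision_idx: list = []

    def predict_proba(self, obs) -> np.ndarray:
        return self.net.forward(np.atleast_2d(obs), training=False)[0]

    def greedy(self, obs) -> int:
        return int(np.argmax(self.predict_proba(obs)))

    def record(self, event: FeedbackEvent) -> None:
        idx = len(self.replay)
        self.replay.append(event)
        (self._collision_idx if event.collision
         else self._noncollision_idx).append(idx)

    def sample_batch(self, rng: np.random.Generator) -> list:
        """Collision-stratified batch: 10% collision / 90% non-collision
        when enough of each exists, otherwise whatever is available."""
        b = self.cfg.batch_size
        n_col = int(round(self.cfg.collision_fraction * b))
        col, non = self._collision_idx, self._noncollision_idx
        take_col = min(n_col, len(col))
        take_non = min(b - take_col, len(non))
        take_col = min(b - take_non, len(col))  # top up if few non-collisions
        chosen = []
        if take_col:
            chosen += [col[i] for i in rng.choice(len(col), size=take_col,
                                                  replace=len(col) < take_col)]
        if take_non:
            chosen += [non[i] for i in rng.choice(len(non), size=take_non,
                                                  replace=False)]
        return [self.replay[i] for i in chosen]

    def train_step(self, batch: list) -> float:
        """One Adam step on a batch of feedback events.

        The executed action's softmax output is pushed toward its binary
        label with binary cross-entropy; other outputs enter only through
        the softmax coupling.
        """
        obs = np.stack([e.state.vector() for e in batch])
        actions = np.array([e.action for e in batch])
        labels = np.array([1.0 if e.label else 0.0 for e in batch])
        p = self.net.forward(obs, training=True)
        n = len(batch)
        rows = np.arange(n)
        pa = np.clip(p[rows, actions], 1e-7, 1 - 1e-7)
        if self.cfg.loss == "executed_bce":
            loss = float(-(labels * np.log(pa)
                           + (1 - labels) * np.log(1 - pa)).mean())
            # dL/dp_a through the softmax: dL/dz_j = g_a * p_a (delta_aj - p_j)
            g_a = (pa - labels) / (pa * (1 - pa)) / n
            dz = -p * (g_a * pa)[:, None]
            dz[rows, actions] += g_a * pa
        elif self.cfg.loss == "one_vs_all_bce":
            # sigmoid reading on the executed logit only
            z = self.net._logits
            za = z[rows, actions]
            s = 1.0 / (1.0 + np.exp(-za))
            loss = float(-(labels * np.log(np.clip(s, 1e-7, None))
                           + (1 - labels)
                           * np.log(np.clip(1 - s, 1e-7, None))).mean())
            dz = np.zeros_like(z)
            dz[rows, actions] = (s - labels) / n
        else:
            raise ValueError(f"unknown loss '{self.cfg.loss}'")
        self.opt.zero_grad()
        self.net.backward(dz)
        self.opt.step()
        return loss

    def save(self, path) -> None:
        import json
        from dataclasses import asdict
        data = {"config": asdict(self.cfg),
                "weights": [w.tolist() for w in self.net.get_weights()]}
        with open(path, "w") as f:
            json.dump(data, f)

    @classmethod
    def load(cls, path) -> "HFPolicy":
        import json
        with open(path) as f:
            data = json.load(f)
        policy = cls(HFConfig(**data["config"]))
        policy.net.set_weights([np.array(w) for w in data["weights"]])
        return policy


def train_hf_policy(world: GridWorld, channel, cfg: HFConfig = HFConfig(),
                    seed: int = 0) -> HFPolicy:
    """Online HF-policy training from a simulated feedback channel.

    The agent acts epsilon-greedily on its improving policy (epsilon decays
    linearly from ``epsilon_start`` to ``epsilon_end`` over the label
    budget; a ``random`` mode keeps actions uniform throughout).  Every
    executed action is judged against the A* oracle, pushed through the
    feedback channel, stored, and the network is updated from stratified
    replay batches.  Training stops after ``cfg.n_labels`` feedback events.

    The returned policy carries ``visited_`` — the (observation, optimal
    action) pairs seen during training — for behavioural evaluation.
    """
    ss = np.random.SeedSequence(seed)
    s_env, s_policy, s_chan, s_batch = ss.spawn(4)
    rng_env = np.random.default_rng(s_env)
    rng_chan = np.random.default_rng(s_chan)
    rng_batch = np.random.default_rng(s_batch)
    policy = HFPolicy(cfg, seed=int(s_policy.generate_state(1)[0] % 2 ** 31))
    if cfg.n_labels < cfg.batch_size:
        raise ValueError("label budget smaller than one batch")

    visited = []
    world.reset(rng=rng_env)
    for k in range(cfg.n_labels):
        frac = k / max(cfg.n_labels - 1, 1)
        eps = cfg.epsilon_start + frac * (cfg.epsilon_end - cfg.epsilon_start)
        obs = world.observe()
        opt = optimal_action(world)
        if opt is None:
            world.reset(rng=rng_env)
            obs = world.observe()
            opt = optimal_action(world)
        if cfg.action_selection == "random" or rng_env.random() < eps:
            action = int(rng_env.integers(N_ACTIONS))
        else:
            action = policy.greedy(obs.vector())
        tr = world.step(action)
        event = oracle_feedback(obs, action, opt, collision=tr.collision)
        event = channel(event, rng_chan)
        policy.record(event)
        visited.append((obs.vector(), int(opt)))
        if len(policy.replay) >= cfg.batch_size:
            for _ in range(cfg.updates_per_event):
                policy.train_step(policy.sample_batch(rng_batch))
        if tr.done:
            world.reset(rng=rng_env)
    policy.visited_ = visited
    return policy


def oracle_agreement(policy: HFPolicy, visited=None) -> float:
    """Fraction of visited states where the greedy HF action equals the
    A*-optimal action."""
    visited = visited if visited is not None else policy.visited_
    if not visited:
        raise ValueError("no visited states recorded")
    hits = sum(policy.greedy(obs) == opt for obs, opt in visited)
    return hits / len(visited)
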