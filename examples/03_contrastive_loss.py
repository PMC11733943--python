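"""The symmetric temperature-scaled contrastive loss on small batches.

Shows the two analytic anchor cases and the effect of temperature on the
logit sharpness.
"""

import numpy as np

import pepclip as pc
from pepclip.autodiff import Tensor

# two perfectly aligned orthonormal pairs: loss = log(1 + e^-1)
batch = pc.LatentBatch(G=Tensor(np.eye(2)), T=Tensor(np.eye(2)))
print("N=2 orthonormal aligned:", float(pc.clip_loss(batch, tau=1.0).data),
      "(closed form:", np.log(1 + np.exp(-1.0)), ")")

# indistinguishable latents: softmax is uniform, loss = log N
ones = np.ones((4, 5))
batch = pc.LatentBatch(G=Tensor(ones), T=Tensor(ones.copy()))
print("N=4 identical latents:", float(pc.clip_loss(batch, tau=1.0).data),
      "(log 4 =", np.log(4.0), ")")

# sharpening the temperature drives the aligned loss toward zero
for tau in (1.0, 0.3, 0.07):
    b = pc.LatentBatch(G=Tensor(np.eye(3)), T=Tensor(np.eye(3)))
    print(f"tau={tau}: aligned 3-pair loss = {float(pc.clip_loss(b, tau).data):.6f}")
# smaller tau scales up the cosine logits, so matched pairs dominate the
# softmax and the loss approaches its lower bound of zero.
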