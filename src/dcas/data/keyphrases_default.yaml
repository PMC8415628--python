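# Default supplemental key-phrase list for the post-classification sweep of
# low-probability narratives.
#
# The original study's full key-phrase list was published only as supplementary
# material that is not available; this shipped list is a RECONSTRUCTION built
# from the cessation phrasings the study itself quotes (e.g. "did not have
# transportation", "loss of driving privileges", "lost his car and could not
# get it back") plus common cessation verb phrases around drive/driving/
# license.  Override it with your own list for real analyses.
#
# Matching is case-insensitive on the raw (unstemmed) narrative text.  A `*`
# stands for a short word gap (one to two words), e.g. "renew * license"
# matches "renew his license".

provenance: reconstructed-default
phrases:
  - "no longer able to drive"
  - "allowed to drive"
  - "could not drive"
  - "no longer drive"
  - "unable to drive"
  - "stop driving"
  - "stopped driving"
  - "license was revoked"
  - "license revoked"
  - "license was suspended"
  - "license suspended"
  - "renew * license"
  - "surrendered * license"
  - "take * license away"
  - "took * license away"
  - "failed * vision test"
  - "vision exam"
  - "did not have transportation"
  - "means of transportation"
  - "driving privileges"
  - "lost * car"
  - "taken away * keys"
  - "took away * keys"
  - "hand over the keys"
  - "operate a vehicle"
  - "give up the car"
  - "behind the wheel"
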