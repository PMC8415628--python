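# Versioned sentence-template pools for the synthetic narrative generator.
#
# Slots: {he} {his} {him} are filled per the decedent's sex; {age} and {race}
# come from the sampled covariates.  Sentences carry no trailing period.
#
# Lexical contract (enforced by tests):
#   * the four seed keywords ("drive", "license", "vision", "dmv") appear, as
#     case-insensitive substrings, ONLY in `cessation_keyword` and
#     `spurious_keyword` sentences;
#   * cessation phrasing appears only in the two cessation pools, so negatives
#     never describe driving cessation.

openers:
  found_states:
    - dead
    - deceased
    - unresponsive
  locations:
    - "in {his} living room"
    - "in the bedroom"
    - "in a wooded area behind the house"
    - "in the garage"
    - "at {his} residence"
    - "in a barn on the property"
    - "near the back porch"
    - "in a motel room"
  causes:
    - "from a gunshot wound to the head"
    - "from a self inflicted gunshot wound"
    - "from an apparent overdose"
    - "from hanging"
    - "from carbon monoxide poisoning"
    - "from a gunshot wound to the chest"

cessation_keyword:
  - "was recently told {he} would no longer be allowed to drive"
  - "had {his} license revoked after a failed vision test"
  - "could no longer drive because of {his} declining health"
  - "was unable to renew {his} license at the DMV"
  - "was told by {his} doctor that {he} could not drive anymore"
  - "failed the vision exam required to keep {his} license"
  - "had {his} license suspended after a DUI arrest"
  - "was afraid to drive and had surrendered {his} license"
  - "worried that the DMV would take {his} license away"
  - "felt there was no point in living if {he} could not drive"

cessation_keyword_free:
  - "no longer had any means of transportation"
  - "had recently lost {his} driving privileges"
  - "lost {his} car and could not get it back"
  - "{his} family had taken away the car keys"
  - "was told to hand over the keys for good"
  - "could no longer operate a vehicle safely"
  - "had to give up the car after years on the road"
  - "relied on others for rides everywhere {he} went"
  - "had stopped getting behind the wheel altogether"
  - "was not permitted to operate {his} truck any longer"

themes:
  functional:
    - "had been struggling with worsening Parkinson disease"
    - "suffered several strokes over the past year"
    - "was losing {his} eyesight to macular degeneration"
    - "could no longer manage daily tasks without help"
    - "had advancing dementia and increasing confusion"
    - "was in chronic pain from a degenerative spine condition"
    - "had severe arthritis that limited {his} mobility"
    - "had recently been diagnosed with a seizure disorder"
    - "was recovering from a heart attack and remained weak"
  accident:
    - "had been involved in a motor vehicle accident last month"
    - "was recently in a collision at an intersection"
    - "had crashed {his} car into a guardrail weeks earlier"
    - "had been in a fender bender that shook {his} confidence"
    - "was cited after a two car accident in town"
    - "had struck a mailbox and damaged the car"
    - "had rolled {his} truck on the highway last fall"
    - "was involved in a wreck that totaled the car"
  substance:
    - "had a long history of alcohol abuse"
    - "had been arrested for DUI twice in recent years"
    - "drank heavily most evenings according to family"
    - "had recently been intoxicated at a family gathering"
    - "had completed an alcohol treatment program last year"
    - "struggled with alcohol dependence for decades"
    - "had been stopped for operating while intoxicated"
    - "family had expressed concern about {his} drinking"
  employment:
    - "worked in commercial trucking for many years"
    - "feared losing {his} job at the delivery company"
    - "had recently been let go from {his} hauling job"
    - "depended on {his} route work for income"
    - "was facing termination after failing a work screening"
    - "had lost {his} commercial certification and with it {his} livelihood"
    - "could not get to work without a car"
    - "had been warned that {his} job was at risk"

spurious_keyword:
  - "was found in the driver's seat of {his} vehicle"
  - "was discovered at the end of the driveway"
  - "the television was still on when {he} was found"
  - "a license plate check identified the vehicle"
  - "had envisioned retiring to the coast someday"
  - "lived on a long gravel drive outside of town"
  - "paperwork from the DMV was found on the kitchen table"
  - "a neighbor saw {him} drive past earlier that morning"

filler:
  - "had a history of depression and hypertension"
  - "had been despondent since {his} spouse passed away"
  - "left a note on the kitchen counter"
  - "had recently been prescribed medication for anxiety"
  - "was reported missing by a family member the day before"
  - "had talked about feeling like a burden"
  - "had financial difficulties after retirement"
  - "was last seen alive the previous evening"
  - "had been sleeping poorly for several weeks"
  - "kept to {him}self in recent months"
  - "had refused to attend a follow up appointment"
  - "was described by neighbors as quiet and private"
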